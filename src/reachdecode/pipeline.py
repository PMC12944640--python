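"""End-to-end orchestration: simulate → preprocess → ERSP → decode →
explain → occlusion → backward control → report.

The run is driven by a YAML configuration (validated with pydantic; field
paths appear in schema errors) and is deterministic for a fixed seed:
per-subject seeds are pre-derived from the global seed, HDF5 datasets are
written without timestamps, and the manifest records a digest of every
tabular/container output so two identical runs compare equal.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .containers import load_epochs, save_epochs
from .explain import (
    EXEC_INTERVAL,
    occlude,
    occlusion_analysis,
    relevance_baseline_test,
    subject_relevance,
)
from .preprocess import condition, make_epochs, preprocess_epochs
from .simulate import SimulationConfig, simulate_continuous, subject_rng
from .spectral import BANDS, band_window_maps, ersp_from_epochs, \
    pairwise_position_tests
from .stats import paired_t
from .train import CHANCE, PROBLEMS, TrainConfig, build_problem, \
    crossval_train, evaluate

log = logging.getLogger("reachdecode")


class SimulationBlock(BaseModel):
    n_subjects: int = 20
    trials_per_target: int = 60
    noise_amp: float = 4.0
    direction_effect: float = 0.6
    effect_jitter: float = 0.0


class PreprocessingBlock(BaseModel):
    band: tuple[float, float] = (1.0, 60.0)
    notch: float = 50.0
    target_sfreq: float = 128.0


class TrainBlock(BaseModel):
    folds: int = 5
    val_fraction: float = 0.2
    lr: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 250


class RunConfig(BaseModel):
    """Validated configuration for a full analysis run."""

    simulation: SimulationBlock = Field(default_factory=SimulationBlock)
    preprocessing: PreprocessingBlock = Field(default_factory=PreprocessingBlock)
    problems: list[str] = ["fine", "coarse", "proximity"]
    train: TrainBlock = Field(default_factory=TrainBlock)
    explain: bool = True
    occlusion: bool = True
    backward_control: bool = True
    ersp: bool = True
    figures: bool = True
    out_dir: str = "runs/latest"
    seed: int = 0

    @field_validator("problems")
    @classmethod
    def _known_problems(cls, v):
        bad = set(v) - set(PROBLEMS)
        if bad:
            raise ValueError(f"unknown problems {sorted(bad)}; "
                             f"choose from {PROBLEMS}")
        if not v:
            raise ValueError("at least one problem required")
        return v


def load_config(path: str | Path) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return RunConfig.model_validate(raw)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _sim_config(cfg: RunConfig) -> SimulationConfig:
    s = cfg.simulation
    return SimulationConfig(
        n_subjects=s.n_subjects, trials_per_target=s.trials_per_target,
        noise_amp=s.noise_amp, direction_effect=s.direction_effect,
        effect_jitter=s.effect_jitter, seed=cfg.seed,
    )


def _train_config(cfg: RunConfig, seed_offset: int = 0) -> TrainConfig:
    t = cfg.train
    return TrainConfig(
        folds=t.folds, val_fraction=t.val_fraction, lr=t.lr,
        batch_size=t.batch_size, max_epochs=t.max_epochs,
        seed=cfg.seed + seed_offset,
    )


def simulate_and_preprocess(cfg: RunConfig, out: Path) -> list[dict]:
    """Stage 1+2: write preprocessed forward/backward containers per subject."""
    sim = _sim_config(cfg)
    epochs_dir = out / "epochs"
    epochs_dir.mkdir(parents=True, exist_ok=True)
    subjects = []
    for i in range(sim.n_subjects):
        t0 = time.time()
        sid = f"S{i:02d}"
        cont, truth = simulate_continuous(sim, sid, rng=subject_rng(sim, i))
        cont = condition(cont, band=cfg.preprocessing.band,
                         notch=cfg.preprocessing.notch)
        fw = make_epochs(cont, "forward")
        bw = make_epochs(cont, "backward_prep")
        fw, bw = preprocess_epochs(fw, bw, cfg.preprocessing.target_sfreq)
        fpath = epochs_dir / f"{sid}_forward.h5"
        bpath = epochs_dir / f"{sid}_backward.h5"
        save_epochs(fw, fpath)
        save_epochs(bw, bpath)
        subjects.append({
            "subject_id": sid, "forward": str(fpath), "backward": str(bpath),
            "truth_informative_interval": list(truth.informative_interval),
            "truth_uninformative_interval": list(truth.uninformative_interval),
        })
        log.info("simulated+preprocessed %s (%.1f s)", sid, time.time() - t0)
    return subjects


def ersp_stage(cfg: RunConfig, out: Path, subjects: list[dict]) -> None:
    """Stage 3: band/window ERSP maps per subject + group statistics."""
    import h5py

    ersp_dir = out / "ersp"
    ersp_dir.mkdir(exist_ok=True)
    band_maps = {b: [] for b in BANDS}
    montage = None
    for rec in subjects:
        fw = load_epochs(rec["forward"])
        montage = fw.montage
        maps = ersp_from_epochs(fw)
        for b in BANDS:
            band_maps[b].append(band_window_maps(maps, b).ersp)
    with h5py.File(ersp_dir / "band_window_maps.h5", "w") as f:
        for b in BANDS:
            f.create_dataset(b, data=np.stack(band_maps[b]),
                             track_times=False)
    rows = []
    n_sub = len(subjects)
    if n_sub >= 2:
        for b in BANDS:
            sm = np.stack(band_maps[b])  # (subj, pos, ch, win)
            for w in range(sm.shape[-1]):
                tests = pairwise_position_tests(sm, window=w, band=b,
                                                seed=cfg.seed)
                for k, (i, j) in enumerate(tests.pairs):
                    for ch in range(sm.shape[2]):
                        if tests.p_raw[k, ch] < 0.5:  # keep the table small
                            rows.append({
                                "band": b, "window": w, "pos_a": i, "pos_b": j,
                                "channel": montage.channel_names[ch],
                                "t": tests.t[k, ch],
                                "p_raw": tests.p_raw[k, ch],
                                "p_fdr": tests.p_fdr[k, ch],
                                "significant": bool(tests.reject[k, ch]),
                            })
    pd.DataFrame(rows).to_csv(ersp_dir / "position_tests.tsv", sep="\t",
                              index=False)
    if cfg.figures and montage is not None:
        from .viz import plot_scalp_map
        import matplotlib.pyplot as plt

        grand = np.stack(band_maps["alpha"]).mean(axis=(0, 1))  # (ch, win)
        fig = plot_scalp_map(
            grand[:, 3], montage,
            title="alpha ERSP, window [-1.5,-1.0] s (grand avg)",
        )
        fig.savefig(ersp_dir / "alpha_prep_scalp.png", dpi=120)
        plt.close(fig)


def decode_stage(cfg: RunConfig, out: Path, subjects: list[dict]):
    """Stage 4: per-subject, per-problem cross-validated decoding."""
    dec_dir = out / "decoding"
    dec_dir.mkdir(exist_ok=True)
    results: dict[str, list] = {p: [] for p in cfg.problems}
    artifacts: dict[str, list] = {p: [] for p in cfg.problems}
    for s_idx, rec in enumerate(subjects):
        fw = load_epochs(rec["forward"])
        for problem in cfg.problems:
            sub = build_problem(fw, problem)
            report, models, test_sets = crossval_train(
                sub, _train_config(cfg, seed_offset=s_idx)
            )
            report.problem = problem
            results[problem].append(report)
            artifacts[problem].append((models, sub, test_sets))
            log.info("decoded %s %s: acc=%.3f (chance %.2f)",
                     rec["subject_id"], problem, report.accuracy,
                     CHANCE[problem])
    rows = []
    for problem in cfg.problems:
        for rep in results[problem]:
            rows.append(rep.summary() | {"chance": CHANCE[problem]})
    df = pd.DataFrame(
        [{k: v for k, v in r.items() if k != "fold_accuracy"} for r in rows]
    )
    df.to_csv(dec_dir / "metrics.tsv", sep="\t", index=False)
    with open(dec_dir / "metrics.json", "w") as f:
        json.dump(rows, f, indent=1, default=float)
    if cfg.figures and rows:
        from .viz import plot_confusion
        import matplotlib.pyplot as plt

        for problem in cfg.problems:
            cm = np.mean([r.confusion for r in results[problem]], axis=0)
            names = artifacts[problem][0][1].label_names
            fig = plot_confusion(cm, names, title=f"{problem} (grand avg)")
            fig.tight_layout()
            fig.savefig(dec_dir / f"confusion_{problem}.png", dpi=120)
            plt.close(fig)
    return results, artifacts


def explain_stage(cfg: RunConfig, out: Path, artifacts) -> None:
    """Stage 5: DeepLIFT relevance maps + baseline statistics."""
    import h5py

    rel_dir = out / "relevance"
    rel_dir.mkdir(exist_ok=True)
    for problem, subj_art in artifacts.items():
        maps = [
            subject_relevance(models, sub, test_sets)
            for models, sub, test_sets in subj_art
        ]
        with h5py.File(rel_dir / f"relevance_{problem}.h5", "w") as f:
            f.create_dataset("spatiotemporal",
                             data=np.stack([m.values for m in maps]),
                             track_times=False)
            f.create_dataset("times", data=maps[0].times, track_times=False)
        if len(maps) >= 2:
            t_times, t_stat, p_raw, p_fdr, rej = relevance_baseline_test(
                maps, seed=cfg.seed
            )
            pd.DataFrame({
                "time": t_times, "t": t_stat, "p_raw": p_raw,
                "p_fdr": p_fdr, "significant": rej,
            }).to_csv(rel_dir / f"baseline_test_{problem}.tsv", sep="\t",
                      index=False)
        if cfg.figures:
            from .viz import plot_relevance_heatmap
            import matplotlib.pyplot as plt

            grand = np.mean([m.values for m in maps], axis=0)
            fig = plot_relevance_heatmap(
                grand, maps[0].times, maps[0].montage,
                title=f"DeepLIFT relevance, {problem} (grand avg)",
            )
            fig.tight_layout()
            fig.savefig(rel_dir / f"relevance_{problem}.png", dpi=120)
            plt.close(fig)


def occlusion_stage(cfg: RunConfig, out: Path, artifacts) -> None:
    """Stage 6: preparation/execution occlusion contrasts."""
    occ_dir = out / "occlusion"
    occ_dir.mkdir(exist_ok=True)
    summary = {}
    for problem, subj_art in artifacts.items():
        models = [a[0] for a in subj_art]
        epochs = [a[1] for a in subj_art]
        tsets = [a[2] for a in subj_art]
        res = occlusion_analysis(models, epochs, tsets)
        summary[problem] = {
            name: {
                "interval": list(r.interval),
                "mean_accuracy_diff": float(r.accuracy_diff.mean()),
                "mean_confusion_diff": r.confusion_diff.mean(axis=0).tolist(),
                "n_significant_cells": (
                    int(r.reject_cells.sum()) if r.reject_cells is not None
                    else None
                ),
            }
            for name, r in res.items()
        }
        rows = []
        for name, r in res.items():
            for s, d in enumerate(r.accuracy_diff):
                rows.append({
                    "problem": problem, "interval": name, "subject": s,
                    "accuracy_intact": r.accuracy_intact[s],
                    "accuracy_occluded": r.accuracy_occluded[s],
                    "accuracy_diff": d,
                })
        pd.DataFrame(rows).to_csv(occ_dir / f"accuracy_{problem}.tsv",
                                  sep="\t", index=False)
    with open(occ_dir / "summary.json", "w") as f:
        json.dump(summary, f, indent=1)


def backward_stage(cfg: RunConfig, out: Path, subjects, artifacts) -> None:
    """Stage 7: backward-preparation decoding + forward-vs-backward table.

    Forward accuracies enter the comparison with the execution interval
    occluded, so both conditions see 2 s of preparation signal only.
    """
    bwd_dir = out / "backward"
    bwd_dir.mkdir(exist_ok=True)
    problems = [p for p in cfg.problems if p in ("coarse", "proximity")]
    rows = []
    for problem in problems:
        fwd_occ_acc, bwd_acc = [], []
        for s_idx, rec in enumerate(subjects):
            models, sub, tsets = artifacts[problem][s_idx]
            occluded = occlude(sub, EXEC_INTERVAL)
            accs = [
                evaluate(m, occluded.data[idx].astype(np.float32),
                         occluded.labels[idx])["accuracy"]
                for m, idx in zip(models, tsets)
            ]
            fwd_occ_acc.append(float(np.mean(accs)))
            bw = load_epochs(rec["backward"])
            bsub = build_problem(bw, problem)
            rep, _, _ = crossval_train(
                bsub, _train_config(cfg, seed_offset=5000 + s_idx)
            )
            bwd_acc.append(rep.accuracy)
        comp = compare_forward_backward(
            np.array(fwd_occ_acc), np.array(bwd_acc)
        )
        rows.append({"problem": problem} | comp)
    pd.DataFrame(rows).to_csv(bwd_dir / "forward_vs_backward.tsv", sep="\t",
                              index=False)


def compare_forward_backward(
    forward_acc: np.ndarray, backward_acc: np.ndarray
) -> dict:
    """Paired comparison of per-subject decoding accuracies.

    ``forward_acc`` must be computed with the execution interval occluded
    so both conditions decode 2 s of preparation activity.
    """
    forward_acc = np.asarray(forward_acc, float)
    backward_acc = np.asarray(backward_acc, float)
    if forward_acc.shape != backward_acc.shape:
        raise ValueError("subject mismatch between conditions")
    out = {
        "n_subjects": int(len(forward_acc)),
        "forward_mean": float(forward_acc.mean()),
        "backward_mean": float(backward_acc.mean()),
        "mean_diff": float((forward_acc - backward_acc).mean()),
    }
    if len(forward_acc) >= 2:
        if np.all(forward_acc == backward_acc):
            out["p"] = 1.0
        else:
            out["p"] = float(paired_t(forward_acc, backward_acc).p_raw)
    return out


def run(config: RunConfig | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages; returns the run manifest."""
    if not isinstance(config, RunConfig):
        config = load_config(config)
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(asctime)s %(message)s")
    # out_dir does not affect the science; keep it out of the config hash
    cfg_text = json.dumps(
        {k: v for k, v in config.model_dump().items() if k != "out_dir"},
        sort_keys=True, default=str,
    )
    stages_done = []
    t_start = time.time()

    subjects = simulate_and_preprocess(config, out)
    stages_done.append("simulate+preprocess")
    if config.ersp:
        ersp_stage(config, out, subjects)
        stages_done.append("ersp")
    results, artifacts = decode_stage(config, out, subjects)
    stages_done.append("decode")
    if config.explain:
        explain_stage(config, out, artifacts)
        stages_done.append("explain")
    if config.occlusion:
        occlusion_stage(config, out, artifacts)
        stages_done.append("occlusion")
    if config.backward_control:
        backward_stage(config, out, subjects, artifacts)
        stages_done.append("backward")

    digests = {
        str(p.relative_to(out)): _digest(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.suffix in (".h5", ".json", ".tsv")
        and p.name != "manifest.json"
    }
    manifest = {
        "config_hash": hashlib.sha256(cfg_text.encode()).hexdigest()[:16],
        "config": config.model_dump(),
        "seed": config.seed,
        "stages": stages_done,
        "outputs": digests,
        "versions": _versions(),
        "elapsed_s": round(time.time() - t_start, 2),
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1, default=str)
    return manifest


def _versions() -> dict:
    import h5py
    import pywt
    import scipy
    import sklearn

    return {
        "reachdecode": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "h5py": h5py.__version__,
        "pywavelets": pywt.__version__,
        "sklearn": sklearn.__version__,
    }
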