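"""Run the complete orchestrated pipeline on a tiny cohort.

Writes epoch containers, ERSP maps with statistics, decoding metrics,
relevance maps, occlusion tables, the forward-vs-backward comparison and
a manifest with output digests into ./scratch/demo_run.  Rerunning with
the same seed reproduces every output bit-for-bit.
"""

from reachdecode.pipeline import RunConfig, run

config = RunConfig.model_validate(dict(
    simulation=dict(n_subjects=2, trials_per_target=8,
                    direction_effect=1.2, noise_amp=1.0),
    problems=["coarse"],
    train=dict(folds=2, max_epochs=10, lr=1e-3, batch_size=8),
    out_dir="scratch/demo_run",
    seed=1,
))
manifest = run(config)
print("\nstages:", ", ".join(manifest["stages"]))
print("outputs:")
for name, digest in manifest["outputs"].items():
    print(f"  {name}  sha256:{digest}")
print(f"\nelapsed: {manifest['elapsed_s']} s; rerunning with the same "
      "config and seed reproduces these digests exactly.")
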