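"""Train the 2.5D network at desk scale and validate on held-out phantoms.

Trains a width-reduced encoder--decoder for 2000 iterations on the slices
of two phantoms (a few minutes on one CPU) and scores five held-out
phantoms through the full predict -> fuse -> measure path.
"""

import numpy as np

from kidneyvol import NetworkSpec, PhantomConfig, build_network, generate_cohort, train
from kidneyvol.model import TrainingConfig
from kidneyvol.validation import _training_samples, aggregate, predict_subject, score_subject

subjects, _ = generate_cohort(7, PhantomConfig.desk_scale(), seed=11)
train_subjects, held_out = subjects[:2], subjects[2:]

spec = NetworkSpec(width_multiplier=0.125, seed=0)
model = build_network(spec)
samples = _training_samples(train_subjects, drop_ends=2, pad_multiple=spec.downsampling_factor)
print(f"training on {len(samples)} slices, {model.n_parameters():,} parameters ...")
model, trace = train(model, samples, TrainingConfig.desk_scale(seed=0))
print(f"cross-entropy: {trace['loss'][:50].mean():.3f} (start) -> {trace['loss'][-50:].mean():.3f} (end)")

rows = [score_subject(predict_subject(model, s).fused_labels, s.truth_fused,
                      s.metadata["subject_id"]) for s in held_out]
for r in rows:
    print(f"{r['subject_id']}: dice {r['dice']:.3f}  "
          f"predicted {r['pred_combined_cm3']:6.1f} cm^3 vs reference {r['ref_combined_cm3']:6.1f} cm^3")
m = aggregate([(r["pred_combined_cm3"], r["ref_combined_cm3"]) for r in rows])
print(f"mean dice {np.mean([r['dice'] for r in rows]):.3f} | MAE {m.mae_cm3:.1f} cm^3 | "
      f"SMAPE {m.smape_pct:.1f}% | LoA ({m.loa_low_cm3:.1f}, {m.loa_high_cm3:.1f}) cm^3")
# Dice measures voxel overlap with the reference mask; the LoA interval
# (reference - predicted) shifts negative when the network oversegments.
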