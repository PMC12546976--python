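"""Planted-module recovery: informed propagation vs classic PageRank.

Runs a small replicate study on fresh synthetic datasets and compares mean
Recall@10 on the held-out module genes (seeds excluded from both rankings).
A matched null — no expression shift, no enriched terms, no dense wiring —
confirms the advantage comes from the planted biology, not the machinery.
"""

from biorank import FixtureConfig, null_config, recovery_experiment

res = recovery_experiment(FixtureConfig(seed=1), replicates=5, k=10)
print("strong planted signal (5 replicates):")
for i, (b, c) in enumerate(zip(res["recall_biorank"], res["recall_classic"])):
    print(f"  replicate {i}: informed Recall@10 = {b:.3f}   "
          f"classic = {c:.3f}")
print(f"  means: informed {res['mean_recall_biorank']:.3f} vs "
      f"classic {res['mean_recall_classic']:.3f} "
      f"(informed wins {res['wins_biorank']}/5)")

null = recovery_experiment(null_config(FixtureConfig(seed=2)),
                           replicates=5, k=10)
print(f"\nmatched null: informed {null['mean_recall_biorank']:.3f} vs "
      f"classic {null['mean_recall_classic']:.3f} "
      f"(wins {null['wins_biorank']}/5, ties {null['ties']}/5)")
print("Under the null neither method can recover the module — both hover"
      "\nnear the chance rate — so the strong-signal gap reflects the"
      "\nbiological evidence channels, not ranking artifacts.")
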