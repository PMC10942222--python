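"""Extract the 63-feature representation from the shipped micro-cohort.

Each case yields 20 per-category counts, 20 total durations, 12 interval
statistics (mean/max/min/SD over the all/left/right event streams), 3
per-minute shift frequencies, 7 dissection/exposure aggregates, and the
manipulation time in minutes.
"""

from surgesture import default_taxonomy, feature_matrix, worked_fixture

tax = default_taxonomy()
cases, _, _ = worked_fixture()
fm = feature_matrix(cases, tax)

print(f"feature matrix: {fm.shape[0]} videos x {fm.shape[1] - 1} features")

v = fm.loc["V007"]  # three hook events at [0,10], [20,30], [50,60]
print("V007 interval stats (gaps 10 s and 20 s):")
for stat in ("mean", "max", "min", "sd"):
    print(f"  int.all.{stat} = {v[f'int.all.{stat}']:.3f} s")

v = fm.loc["V003"]  # all-dissection case: exposure denominator floored at 1 s
print(f"V003 D/E duration ratio (no exposure events): {v['de.dur_ratio']:.1f}")
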