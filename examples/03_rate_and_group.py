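"""Aggregate two-rater mGOALS scores, verify agreement, derive skill groups.

Surgeons below the first quartile of their mean case score form the
incompetent group; agreement between the raters is checked with ICC(2,1)
(qualification threshold 0.75) and Kendall's W.
"""

from surgesture import (CohortConfig, case_scores, generate_cohort,
                        icc_absolute_agreement, kendalls_w, quantile_grouping,
                        surgeon_scores)
from surgesture.rating import ratings_table

cases, ratings, _ = generate_cohort(CohortConfig(seed=7, n_videos=75, n_surgeons=33))

wide = ratings_table(ratings).pivot(index="rater_id", columns="video_id",
                                    values="total")
icc, qualified = icc_absolute_agreement(wide.to_numpy())
print(f"ICC(2,1) between raters: {icc:.3f} "
      f"({'qualified' if qualified else 'below threshold'})")
print(f"Kendall's W:             {kendalls_w(wide.to_numpy()):.3f}")

scores = case_scores(ratings)
surgeon_of = {c.video_id: c.surgeon_id for c in cases}
ss = surgeon_scores(scores.loc[[c.video_id for c in cases]], surgeon_of)
grouping = quantile_grouping(ss)
print(f"quartile cuts: q1 = {grouping.q1_cut:.2f}, q3 = {grouping.q3_cut:.2f}")
sizes = {g: sum(v == g for v in grouping.group.values()) for g in ("top", "medium", "bottom")}
print(f"surgeons per level: {sizes}  "
      f"(bottom level = incompetent; top + medium = competent)")
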