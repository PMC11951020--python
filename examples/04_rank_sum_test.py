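"""Wilcoxon rank-sum behaviour: exact vs normal approximation.

Small pooled samples are tested by complete enumeration of rank
assignments; larger ones by a tie-corrected normal approximation with
continuity correction.
"""

import numpy as np

from paskin import rank_sum_test

# textbook case: x occupies the two smallest ranks of four
p = rank_sum_test([1, 2], [3, 4])
print(f"x={{1,2}} vs y={{3,4}}: exact two-sided p = {p:.4f} (= 1/3)")

rng = np.random.default_rng(0)
x = rng.normal(0.0, 1.0, 6)
y = rng.normal(1.0, 1.0, 6)
print(f"n=6+6 shifted normals: exact p = {rank_sum_test(x, y):.4f}, "
      f"approx p = {rank_sum_test(x, y, exact_max_pooled=0):.4f}")

x = rng.normal(0.173, 0.061, 36)
y = rng.normal(0.342, 0.099, 17)
print(f"n=36 vs 17 (boundary-slope-like separation): p = "
      f"{rank_sum_test(x, y):.2e}")
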