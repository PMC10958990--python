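"""Midpoint-elevation ANCOVA: recovering a known between-group strength offset.

Two groups share the strength-aBMD slope but one is offset by 1045 N.  The
comparison tests slope equality (interaction F-test), elevation equality
(group term in the common-slope model), and reads per-group elevations off
regressions refit after shifting x by the midpoint of the pooled range.  The
percent difference uses the percent-of-mean convention.
"""

import numpy as np

from pseudodxa import ancova_compare

rng = np.random.default_rng(7)
n = 50
abmd_f = rng.normal(29.1, 6.2, n)   # female-like aBMD distribution
abmd_m = rng.normal(36.6, 7.0, n)   # male-like
strength_f = 500.0 + 105.0 * abmd_f + rng.normal(0, 750, n)
strength_m = 500.0 + 105.0 * abmd_m + 1045.0 + rng.normal(0, 750, n)

x = np.concatenate([abmd_f, abmd_m])
y = np.concatenate([strength_f, strength_m])
group = np.repeat([0, 1], n)  # female = 0, male = 1

res = ancova_compare(x, y, group)
print(f"slope-equality p      : {res.slope_p:.3f}   (no true slope difference)")
print(f"elevation-equality p  : {res.elevation_p:.2e} (true 1045 N offset)")
print(f"common slope          : {res.common_slope:.1f} N per aBMD unit")
print(f"female elevation      : {res.elevations[0]:7.1f} N  CI {res.elevation_cis[0]}")
print(f"male elevation        : {res.elevations[1]:7.1f} N  CI {res.elevation_cis[1]}")
print(f"difference            : {res.elevation_diff:7.1f} N  CI {res.elevation_diff_ci}")
print(f"percent-of-mean diff  : {res.pct_difference:5.1f} %")
print("\nThe recovered difference estimates the injected 1045 N offset; its 95%")
print("CI covers the truth ~95% of the time over repeated simulations.")
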