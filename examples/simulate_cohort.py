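"""Generate a synthetic mCRPC cohort and check its calibration.

The generator draws biomarker profiles at the configured marginal
prevalences, ctDNA-fraction bands, prior-exposure flags and Poisson-process
accrual times.  With the default scenario the shares below should sit near
39% AR-negative/TP53-wild-type, 45% TP53-altered, 12% HRD, 31% fusion-
positive, and bands near 27/54/19%.
"""

import numpy as np

from adaptrial.cohort import default_scenario, generate_cohort

scenario = default_scenario()
cohort = generate_cohort(scenario, n=2000, rng=1)

profiles = [p.profile for p in cohort]
share = lambda flag: 100 * np.mean([flag(p) for p in profiles])

print(f"patients: {len(cohort)}, accrual span: {cohort[-1].entry_time:.1f} months")
print(f"AR-neg & TP53-wt : {share(lambda p: not p.ar_positive and not p.tp53_altered):.1f}%")
print(f"TP53-altered     : {share(lambda p: p.tp53_altered):.1f}%")
print(f"HRD              : {share(lambda p: p.hrd):.1f}%")
print(f"TMPRSS2-ERG      : {share(lambda p: p.terg_positive):.1f}%")
for band in ("low", "medium", "high"):
    print(f"ctDNA band {band:<7}: {share(lambda p, b=band: p.ctdna_band == b):.1f}%")
print(f"prior ARPI       : {100 * np.mean([p.prior_arpi for p in cohort]):.1f}%")
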