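"""Associate proteoform thermal stability with drug sensitivity.

Thermal stability (melting AUC per cell line) of one proteoform is made
linearly predictive of sensitivity to one drug; 29 other drugs are pure
noise.  Ordinary least squares plus joint Benjamini-Hochberg adjustment
recovers the planted association.
"""

import numpy as np
import pandas as pd

from meltforms import associate, filter_drugs

rng = np.random.default_rng(4)
lines = [f"CL{i:02d}" for i in range(18)]

auc = pd.DataFrame(rng.normal(19.0, 0.8, (3, 18)),
                   index=["PF1_1", "PF2_1", "PF3_2"], columns=lines)
sdss = pd.DataFrame(rng.normal(2.0, 3.0, (18, 30)), index=lines,
                    columns=[f"drug{i:02d}" for i in range(30)])
sdss["drug00"] = 4.0 * (auc.loc["PF1_1"] - 19.0) + 6.0 + rng.normal(0, 0.5, 18)

sdss = filter_drugs(sdss, min_max_sdss=6.0)
records = associate(auc, sdss, alpha=0.1)
hits = [r for r in records if r.significant]
print(f"{len(records)} proteoform x drug tests, {len(hits)} significant")
for r in hits:
    print(f"{r.proteoform_id} ~ {r.drug_id}: slope {r.slope:.2f}, "
          f"r {r.pearson_r:.3f}, p_adj {r.p_adj:.2e}")
# Only the planted PF1_1 ~ drug00 pair should survive the adjustment:
# cell lines in which the proteoform is more thermally stable are more
# sensitive to the drug.
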