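"""The abundance-decoupled redox call, step by step.

A Cys site's HPE-IAM-alkylated peptide intensity reports its *reduced*
fraction, so an intensity increase means the site became less oxidized.  A
redox call needs (a) raw t-test p < 0.05, (b) |fold change| > 1.5, and (c) a
parent protein whose own abundance did not change (|fold| < 1.5), so that the
call reflects oxidation state, not expression.
"""

import numpy as np
import pandas as pd

import redoxquant as rq

cfg = rq.PipelineConfig()  # fc 1.5, alpha 0.05, decoupling on the fold scale

cases = pd.DataFrame(
    [
        # fcs = signed fold change of summed HPE-IAM-Cys intensity
        {"accession": "DLDH", "site_key": "C42_C47", "fold_change_signed": 6.37, "p": 0.004},
        {"accession": "KAT", "site_key": "C109", "fold_change_signed": 18.5, "p": 0.002},
        {"accession": "FBA", "site_key": "C112", "fold_change_signed": -2.1, "p": 0.01},
        {"accession": "ACAA", "site_key": "C30", "fold_change_signed": 3.0, "p": 0.01},
        {"accession": "PGM", "site_key": "C77", "fold_change_signed": -1.9, "p": 0.30},
    ]
)
cases["log2fc"] = np.sign(cases["fold_change_signed"]) * np.log2(
    cases["fold_change_signed"].abs()
)
cases["tested"] = True

# parent protein abundance results: ACAA itself is 2.5-fold up, others stable
parents = pd.DataFrame(
    [
        {"accession": "DLDH", "log2fc": 0.10, "tested": True},
        {"accession": "KAT", "log2fc": -0.20, "tested": True},
        {"accession": "FBA", "log2fc": 0.05, "tested": True},
        {"accession": "ACAA", "log2fc": np.log2(2.5), "tested": True},
        {"accession": "PGM", "log2fc": 0.00, "tested": True},
    ]
)

called = rq.call_site_redox(cases, parents, cfg)
print(called[["accession", "site_key", "fold_change_signed", "p", "protein_log2fc", "call"]]
      .to_string(index=False))

# DLDH and KAT: intensity up on stable proteins -> less_oxidized.
# FBA: intensity down -> more_oxidized.
# ACAA: passes (a) and (b) but its protein is 2.5-fold up -> the change is
#       abundance-coupled, not a redox call.
# PGM: p = 0.30 fails the significance gate -> ns.
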