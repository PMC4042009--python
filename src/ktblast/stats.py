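"""Agreement statistics: Bland-Altman analysis and paired t tests.

Limits of agreement are bias +/- 2 SD of the paired differences (sample SD,
n-1 denominator); significance of a bias is a two-tailed one-sample t test
of the differences against zero.  Comparisons between protocols applied to
the same subjects use the paired two-sample t test.  No multiple-testing
correction is applied across indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["AgreementReport", "bland_altman", "two_sample_t"]


@dataclass
class AgreementReport:
    index_name: str
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    p_value: float
    n: int
    degenerate_variance: bool = False

    def as_dict(self) -> dict:
        return {
            "index": self.index_name, "bias": self.bias, "sd": self.sd_diff,
            "loa_low": self.loa_low, "loa_high": self.loa_high,
            "p": self.p_value, "n": self.n,
        }


def bland_altman(test, reference, index_name: str = "") -> AgreementReport:
    """Bias, SD and +/-2 SD limits of paired differences (test - reference)."""
    test = np.asarray(test, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if test.shape != reference.shape:
        raise ValueError("test and reference must have equal length")
    n = test.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = test - reference
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    degenerate = sd == 0.0
    if degenerate:
        p = 1.0
    else:
        p = float(sps.ttest_1samp(d, 0.0).pvalue)
    return AgreementReport(
        index_name=index_name, bias=bias, sd_diff=sd,
        loa_low=bias - 2.0 * sd, loa_high=bias + 2.0 * sd,
        p_value=p, n=n, degenerate_variance=degenerate,
    )


def two_sample_t(a, b, paired: bool = True) -> float:
    """Two-tailed t-test p-value; paired by default (same subjects per arm)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired test requires equal-length samples")
        d = a - b
        if d.std(ddof=1) == 0.0:
            return 1.0 if d.mean() == 0.0 else 0.0
        return float(sps.ttest_rel(a, b).pvalue)
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(sps.ttest_ind(a, b).pvalue)
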