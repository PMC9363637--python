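"""Mid-parent heterosis statistics and the 2^-ddCt qPCR fold change.

Heterosis is the percentage deviation of the F1 hybrid mean from the
mid-parent value,

    H% = (F1_mean - MP) / MP * 100,   MP = (PM_mean + PF_mean) / 2,

positive when the hybrid exceeds the parental average. Significance is
assessed with a one-sample t statistic of the F1 values against the
mid-parent value, t = (F1_mean - MP) / (s_F1 / sqrt(N)), df = N - 1,
treating the parental means as fixed constants. The t formula as commonly
printed in the crossbreeding literature is typographically ambiguous; a
literal token-order transcription is available via ``method="literal"``
for comparison but is not endorsed (it is not scale invariant).
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class HeterosisResult:
    trait: str
    cross: str
    f1_mean: float
    pm_mean: float
    pf_mean: float
    midparent: float
    n: int
    f1_sd: float
    h_percent: float
    t_stat: float
    df: int
    p_value: float
    #: True when f1_sd == 0 and F1 mean differs from the mid-parent; the
    #: reported p is then the machine minimum rather than an exact value.
    p_underflow: bool = False


def heterosis_test(
    f1_values,
    pm_values,
    pf_values,
    trait: str = "",
    cross: str = "",
    method: str = "delta",
) -> HeterosisResult:
    """Mid-parent heterosis H% with its t test for one trait and one cross.

    Parameters
    ----------
    f1_values, pm_values, pf_values
        Per-individual phenotypes for the cross, the maternal purebred and
        the paternal purebred; each needs at least two values.
    method
        ``"delta"`` (default): t = (F1_mean - MP)/(s_F1/sqrt(N)).
        ``"literal"``: token-order transcription of the published formula,
        t = H%^2 * sqrt(SS/(N-1)) / ((PM + PF) * N); sign-consistent with
        the default but dimensionally inconsistent — comparison only.
    """
    f1 = np.asarray(f1_values, dtype=float)
    pm = np.asarray(pm_values, dtype=float)
    pf = np.asarray(pf_values, dtype=float)
    for name, arr in (("f1", f1), ("pm", pm), ("pf", pf)):
        if arr.size < 2:
            raise ValueError(f"{name} group needs at least 2 values")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite value in {name} group")
    if method not in ("delta", "literal"):
        raise ValueError(f"unknown method {method!r}")

    f1_mean = float(f1.mean())
    pm_mean = float(pm.mean())
    pf_mean = float(pf.mean())
    midparent = (pm_mean + pf_mean) / 2.0
    if midparent == 0:
        raise ValueError("mid-parent value is zero; H% undefined")

    n = int(f1.size)
    f1_sd = float(f1.std(ddof=1))
    h_percent = (f1_mean - midparent) / midparent * 100.0
    df = n - 1
    underflow = False

    if f1_sd == 0.0:
        if f1_mean == midparent:
            t_stat, p_value = 0.0, 1.0
        else:
            t_stat = math.copysign(math.inf, f1_mean - midparent)
            p_value = sys.float_info.min
            underflow = True
    elif method == "delta":
        t_stat = (f1_mean - midparent) / (f1_sd / math.sqrt(n))
        p_value = float(2.0 * stats.t.sf(abs(t_stat), df))
    else:  # literal
        ss = float(((f1 - f1_mean) ** 2).sum())
        t_stat = h_percent**2 * math.sqrt(ss / (n - 1)) / ((pm_mean + pf_mean) * n)
        t_stat = math.copysign(t_stat, f1_mean - midparent)
        p_value = float(2.0 * stats.t.sf(abs(t_stat), df))
    p_value = min(max(p_value, sys.float_info.min), 1.0)

    return HeterosisResult(
        trait=trait,
        cross=cross,
        f1_mean=f1_mean,
        pm_mean=pm_mean,
        pf_mean=pf_mean,
        midparent=midparent,
        n=n,
        f1_sd=f1_sd,
        h_percent=h_percent,
        t_stat=t_stat,
        df=df,
        p_value=p_value,
        p_underflow=underflow,
    )


def ddct_fold_change(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative qPCR fold change by the 2^-ddCt method.

    ddCt = (Ct_target,case - Ct_ref,case) - (Ct_target,ctrl - Ct_ref,ctrl);
    fold = 2**(-ddCt). A one-cycle lower ddCt doubles the fold change.
    """
    cts = (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)
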