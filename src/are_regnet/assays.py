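"""Downstream assay computations: 2^-ddCt relative expression and
actinomycin-D mRNA decay kinetics.

Relative expression between conditions is quantified from qPCR cycle
thresholds by the 2^-ddCt method (amplification efficiency assumed 2).
Decay constants come from a log-linear least-squares fit ln a(t) = -k t + c
of transcription-arrested time courses; half-life is t1/2 = ln2 / k.  Two
conditions are compared by testing the condition x time interaction in a
joint log-linear regression (the slope-difference test), with
Benjamini-Hochberg control across genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CtRecord",
    "DecayFit",
    "ddct_fold_change",
    "fold_change_table",
    "fit_decay",
    "compare_decay",
    "compare_decay_table",
]


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement: target and reference Ct for a gene/condition."""

    gene: str
    condition: str
    ct_target: float
    ct_reference: float
    replicate: int = 1

    def __post_init__(self) -> None:
        for label, v in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{label} must be positive and finite, got {v}")

    @property
    def dct(self) -> float:
        return self.ct_target - self.ct_reference


def ddct_fold_change(control: CtRecord, treated: CtRecord) -> float:
    """Fold change 2^-(dCt_treated - dCt_control); dCt = Ct_target - Ct_ref."""
    if control.gene != treated.gene:
        raise ValueError(
            f"gene mismatch: control {control.gene!r} vs treated {treated.gene!r}"
        )
    ddct = treated.dct - control.dct
    return 2.0 ** (-ddct)


def fold_change_table(
    ct: pd.DataFrame, control: str = "control", treated: str = "treated"
) -> pd.DataFrame:
    """Per-gene ddCt and fold change from a Ct table with columns gene,
    condition, replicate, ct_target, ct_reference (dCt averaged over
    replicates within each condition)."""
    required = {"gene", "condition", "ct_target", "ct_reference"}
    if not required <= set(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    dct = (
        ct.assign(dct=ct["ct_target"] - ct["ct_reference"])
        .groupby(["gene", "condition"])["dct"]
        .mean()
        .unstack("condition")
    )
    for cond in (control, treated):
        if cond not in dct.columns:
            raise ValueError(f"condition {cond!r} absent from Ct table")
    ddct = dct[treated] - dct[control]
    return pd.DataFrame({"ddct": ddct, "fold_change": 2.0 ** (-ddct)})


@dataclass(frozen=True)
class DecayFit:
    """First-order decay fit; ``no_decay`` flags k <= 0 (half-life undefined)."""

    gene: str
    condition: str
    k: float
    half_life: float | None
    stderr: float
    n_obs: int
    no_decay: bool


def _check_timecourse(tc: pd.DataFrame) -> pd.DataFrame:
    required = {"time_h", "abundance"}
    if not required <= set(tc.columns):
        raise ValueError(f"time course must have columns {sorted(required)}")
    if (tc["abundance"] <= 0).any():
        raise ValueError("abundances must be positive")
    if tc["time_h"].nunique() < 3:
        raise ValueError("decay fitting requires at least 3 distinct time points")
    if 0.0 not in tc["time_h"].to_numpy():
        raise ValueError("time course must include t=0")
    return tc


def fit_decay(tc: pd.DataFrame) -> DecayFit:
    """Pooled least-squares fit of ln(abundance) = -k*t + c.

    Abundances are first normalised to the mean at t=0, matching relative
    qRT-PCR quantification.  k <= 0 (including exactly constant abundance)
    is reported as no detectable decay.
    """
    tc = _check_timecourse(tc)
    gene = str(tc["gene"].iloc[0]) if "gene" in tc.columns else ""
    condition = str(tc["condition"].iloc[0]) if "condition" in tc.columns else ""
    a = tc["abundance"].to_numpy(dtype=np.float64)
    t = tc["time_h"].to_numpy(dtype=np.float64)
    a = a / a[t == 0.0].mean()
    log_a = np.log(a)
    if np.ptp(log_a) == 0.0:
        return DecayFit(gene, condition, 0.0, None, 0.0, t.size, no_decay=True)
    fit = stats.linregress(t, log_a)
    k = -float(fit.slope)
    if k <= 0:
        return DecayFit(gene, condition, k, None, float(fit.stderr), t.size, no_decay=True)
    return DecayFit(
        gene, condition, k, math.log(2.0) / k, float(fit.stderr), t.size, no_decay=False
    )


def compare_decay(tc_a: pd.DataFrame, tc_b: pd.DataFrame) -> dict[str, float]:
    """Slope-difference test between two decay time courses.

    Fits the joint model ln a = b0 + b1*t + b2*cond + b3*(t*cond) by OLS and
    reports delta_k = k_b - k_a = -b3 with the two-sided t-test p-value of
    the interaction coefficient.
    """
    import statsmodels.api as sm

    fits = [fit_decay(tc) for tc in (tc_a, tc_b)]  # validates both conditions
    frames = []
    for cond_code, tc in ((0.0, tc_a), (1.0, tc_b)):
        t = tc["time_h"].to_numpy(dtype=np.float64)
        a = tc["abundance"].to_numpy(dtype=np.float64)
        a = a / a[t == 0.0].mean()
        frames.append(
            pd.DataFrame({"log_a": np.log(a), "t": t, "cond": cond_code})
        )
    df = pd.concat(frames, ignore_index=True)
    X = sm.add_constant(
        pd.DataFrame({"t": df["t"], "cond": df["cond"], "t_cond": df["t"] * df["cond"]})
    )
    res = sm.OLS(df["log_a"], X).fit()
    b3 = float(res.params["t_cond"])
    return {
        "delta_k": -b3,
        "p_value": float(res.pvalues["t_cond"]),
        "k_a": fits[0].k,
        "k_b": fits[1].k,
    }


def compare_decay_table(
    tc: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Per-gene slope-difference tests with Benjamini-Hochberg control.

    ``tc`` holds both conditions (columns gene, condition, time_h,
    abundance).  Returns a gene-indexed table with delta_k, p_value, q_value
    and the FDR flag.
    """
    rows = []
    for gene, sub in tc.groupby("gene"):
        a = sub[sub["condition"] == condition_a]
        b = sub[sub["condition"] == condition_b]
        if a.empty or b.empty:
            raise ValueError(f"gene {gene!r} lacks one of the conditions")
        res = compare_decay(a, b)
        rows.append({"gene": gene, **res})
    out = pd.DataFrame(rows).set_index("gene")
    rejected, q, _, _ = multipletests(out["p_value"], alpha=fdr, method="fdr_bh")[0:4]
    out["q_value"] = q
    out["significant"] = rejected
    return out
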