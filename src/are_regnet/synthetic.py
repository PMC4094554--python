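"""Synthetic data generators for every pipeline input.

These generators emulate the statistical roles of the study conditions the
pipeline was designed for: a large log-scale expression matrix containing an
ARE-binding regulator with planted linear (negative-slope, i.e. inversely
correlated) and nonlinear target dependencies among independent background
genes; 3'UTR sequences with a controlled number of planted 13-bp ARE motif
copies and a motif-free background; knockout-style validation gene sets
overlapping the planted targets; exponential mRNA decay time courses with
multiplicative lognormal noise; and qPCR Ct tables with a planted ddCt.

Every generator is deterministic under its seed.  The nonlinear dependency
forms are even functions of the regulator (parabola, cosine, absolute value),
so their Pearson correlation with the regulator vanishes by symmetry while
their MIC stays high -- the contrast the dependency metrics are compared on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneSet
from .motif import ARE_CONSENSUS, MotifPattern, scan_sequence

__all__ = [
    "SyntheticConfig",
    "UtrSpec",
    "gen_expression",
    "gen_utr_fasta",
    "gen_validation_geneset",
    "gen_decay_timecourse",
    "gen_qpcr_table",
]

NONLINEAR_FORMS = ("parabola", "sinusoid", "absolute_value")


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the synthetic expression matrix."""

    n_genes: int = 500
    n_samples: int = 200
    regulator_id: str = "ZFP36L1"
    n_linear_targets: int = 5
    n_nonlinear_targets: int = 0
    noise_sd: float = 0.5
    linear_slope: float = -2.0
    nonlinear_form: str = "parabola"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_samples < 1:
            raise ValueError("n_genes must be >= 2 and n_samples >= 1")
        if self.n_linear_targets < 0 or self.n_nonlinear_targets < 0:
            raise ValueError("target counts must be non-negative")
        if self.n_linear_targets + self.n_nonlinear_targets >= self.n_genes:
            raise ValueError("n_linear_targets + n_nonlinear_targets must be < n_genes")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.nonlinear_form not in NONLINEAR_FORMS:
            raise ValueError(
                f"nonlinear_form must be one of {NONLINEAR_FORMS}, got {self.nonlinear_form!r}"
            )


def _nonlinear(form: str, x: np.ndarray) -> np.ndarray:
    # centred even functions of a standard normal regulator
    if form == "parabola":
        return x**2 - 1.0
    if form == "sinusoid":
        return np.cos(np.pi * x) - math.exp(-np.pi**2 / 2.0)
    return np.abs(x) - math.sqrt(2.0 / np.pi)  # absolute_value


def gen_expression(config: SyntheticConfig) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Expression matrix (genes x samples) plus the planted-target truth.

    The regulator row is N(0,1); each linear target is
    ``linear_slope * regulator + noise``; each nonlinear target is a centred
    even function of the regulator plus noise; background genes are
    independent N(0,1).  Returns ``(matrix, truth)`` with truth keys
    ``linear`` and ``nonlinear``.
    """
    rng = np.random.default_rng(config.seed)
    reg = rng.standard_normal(config.n_samples)
    lin_ids = [f"TGT_LIN_{i + 1:03d}" for i in range(config.n_linear_targets)]
    nl_ids = [f"TGT_NL_{i + 1:03d}" for i in range(config.n_nonlinear_targets)]
    n_bg = config.n_genes - 1 - len(lin_ids) - len(nl_ids)
    bg_ids = [f"BG_{i + 1:05d}" for i in range(n_bg)]

    rows = {config.regulator_id: reg}
    for g in lin_ids:
        rows[g] = config.linear_slope * reg + config.noise_sd * rng.standard_normal(
            config.n_samples
        )
    base = _nonlinear(config.nonlinear_form, reg)
    for g in nl_ids:
        rows[g] = base + config.noise_sd * rng.standard_normal(config.n_samples)
    for g in bg_ids:
        rows[g] = rng.standard_normal(config.n_samples)

    samples = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    matrix = pd.DataFrame(rows, index=samples).T
    matrix.index.name = "gene"
    truth = {"linear": lin_ids, "nonlinear": nl_ids}
    return matrix, truth


@dataclass(frozen=True)
class UtrSpec:
    """One synthetic 3'UTR: length, number of planted ARE copies, alphabet."""

    gene: str
    length: int = 1000
    planted_copies: int = 0
    alphabet: str = "DNA"

    def __post_init__(self) -> None:
        if self.alphabet not in ("DNA", "RNA"):
            raise ValueError(f"alphabet must be DNA or RNA, got {self.alphabet!r}")
        if self.planted_copies < 0:
            raise ValueError("planted_copies must be >= 0")
        if self.planted_copies * len(ARE_CONSENSUS) > self.length:
            raise ValueError(
                f"{self.gene}: length {self.length} too small for "
                f"{self.planted_copies} motif copies"
            )


def _motif_instance(rng: np.random.Generator) -> str:
    # expand each W of the consensus independently to A or T
    return "".join(
        ("A" if rng.integers(2) == 0 else "T") if c == "W" else ("T" if c == "U" else c)
        for c in ARE_CONSENSUS
    )


def gen_utr_fasta(
    specs: list[UtrSpec], seed: int = 0, max_tries: int = 200
) -> tuple[dict[str, str], pd.DataFrame]:
    """Synthetic 3'UTRs with exactly the planted motif copies.

    Background composition is uniform over the four bases; each candidate
    sequence is re-scanned and rejection-sampled until the scanner reports
    exactly the planted hits, so the background is guaranteed motif-free.
    Returns ``(sequences, truth)`` where truth lists 1-based start positions.
    """
    pattern = MotifPattern(ARE_CONSENSUS)
    k = len(pattern)
    sequences: dict[str, str] = {}
    rows = []
    rng = np.random.default_rng(seed)
    for spec in specs:
        bases = "ACGT" if spec.alphabet == "DNA" else "ACGU"
        accepted = None
        for _ in range(max_tries):
            seq = rng.choice(list(bases), size=spec.length)
            # non-overlapping planted windows, uniformly spaced slots
            starts: list[int] = []
            if spec.planted_copies:
                slot = spec.length // spec.planted_copies
                for c in range(spec.planted_copies):
                    lo = c * slot
                    hi = min((c + 1) * slot, spec.length) - k
                    starts.append(int(rng.integers(lo, hi + 1)))
            instances = []
            for s in starts:
                inst = _motif_instance(rng)
                if spec.alphabet == "RNA":
                    inst = inst.replace("T", "U")
                seq[s : s + k] = list(inst)
                instances.append(inst)
            cand = "".join(seq)
            found = scan_sequence(cand, pattern, gene=spec.gene)
            if [h[0] for h in found.hits] == [s + 1 for s in starts]:
                accepted = (cand, starts, instances)
                break
        if accepted is None:
            raise RuntimeError(f"{spec.gene}: could not generate a motif-clean sequence")
        cand, starts, instances = accepted
        sequences[spec.gene] = cand
        for s, inst in zip(starts, instances):
            rows.append({"gene": spec.gene, "start": s + 1, "match": inst})
    truth = pd.DataFrame(rows, columns=["gene", "start", "match"])
    return sequences, truth


def gen_validation_geneset(
    planted_targets,
    n_true_in_set: int,
    n_decoys: int,
    universe,
    seed: int = 0,
    name: str = "validation",
    description: str = "synthetic knockout-derived validation set",
) -> GeneSet:
    """Validation gene set overlapping the planted targets, padded with
    decoys drawn from the universe minus the planted targets."""
    planted = list(planted_targets)
    if n_true_in_set > len(planted):
        raise ValueError(
            f"n_true_in_set={n_true_in_set} exceeds the {len(planted)} planted targets"
        )
    pool = sorted(set(universe) - set(planted))
    if n_decoys > len(pool):
        raise ValueError(f"universe too small: {len(pool)} decoy candidates < {n_decoys}")
    rng = np.random.default_rng(seed)
    true_part = list(rng.choice(planted, size=n_true_in_set, replace=False)) if n_true_in_set else []
    decoy_part = list(rng.choice(pool, size=n_decoys, replace=False)) if n_decoys else []
    members = tuple(true_part + decoy_part)
    return GeneSet(name=name, description=description, genes=members)


def gen_decay_timecourse(
    half_life: float,
    timepoints=(0.0, 2.0, 4.0),
    noise_cv: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    gene: str = "BCL2",
    condition: str = "control",
    no_decay: bool = False,
) -> pd.DataFrame:
    """First-order decay time course with multiplicative lognormal noise.

    Relative abundance a(t) = exp(-(ln2 / half_life) * t), multiplied by a
    mean-1 lognormal with coefficient of variation ``noise_cv``, then
    normalised so the mean abundance at t=0 is exactly 1.  ``no_decay``
    (the half_life -> infinity limit) yields constant abundance 1.
    """
    timepoints = [float(t) for t in timepoints]
    if not no_decay and not half_life > 0:
        raise ValueError(f"half_life must be positive, got {half_life}")
    if 0.0 not in timepoints:
        raise ValueError("timepoints must include t=0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    k = 0.0 if (no_decay or math.isinf(half_life)) else math.log(2.0) / half_life
    sigma = math.sqrt(math.log(1.0 + noise_cv**2))
    rows = []
    for rep in range(1, n_replicates + 1):
        for t in timepoints:
            a = math.exp(-k * t)
            if noise_cv > 0:
                a *= rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma)
            rows.append(
                {
                    "gene": gene,
                    "condition": condition,
                    "replicate": rep,
                    "time_h": t,
                    "abundance": a,
                }
            )
    df = pd.DataFrame(rows)
    t0_mean = df.loc[df["time_h"] == 0.0, "abundance"].mean()
    df["abundance"] /= t0_mean
    return df


def gen_qpcr_table(
    ddct_truth: dict[str, float],
    base_ct: float = 20.0,
    target_offset: float = 3.0,
    n_replicates: int = 1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Ct table (target/reference x control/treated) consistent with the
    planted ddCt per gene: treated dCt = control dCt + ddCt."""
    if base_ct <= 0:
        raise ValueError("base_ct must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for gene, ddct in ddct_truth.items():
        for rep in range(1, n_replicates + 1):
            for condition, extra in (("control", 0.0), ("treated", float(ddct))):
                ct_ref = base_ct + noise_sd * rng.standard_normal()
                ct_tgt = base_ct + target_offset + extra + noise_sd * rng.standard_normal()
                rows.append(
                    {
                        "gene": gene,
                        "condition": condition,
                        "replicate": rep,
                        "ct_target": ct_tgt,
                        "ct_reference": ct_ref,
                    }
                )
    return pd.DataFrame(rows)
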