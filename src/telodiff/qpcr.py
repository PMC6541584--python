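"""Efficiency-corrected relative qPCR expression with a pairwise fixed
reallocation randomisation test.

The relative expression of a target gene in the case group versus the
control group, normalised to a reference (housekeeping) gene, is

    ratio = E_target ** dCq_target / E_ref ** dCq_ref,

where ``dCq = meanCq_control - meanCq_case`` (replicate wells averaged per
sample first, then averaged within group) and ``E`` is the per-gene
amplification efficiency (2.0 = perfect doubling). Significance comes from
reallocating the sample group labels, preserving group sizes, and
recomputing |log2 ratio|; the test switches to exhaustive enumeration when
the number of distinct reallocations is small enough.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ValidationError

logger = logging.getLogger("telodiff")

WELL_COLUMNS = ["sample", "group", "gene", "replicate", "cq"]


@dataclass
class QpcrTable:
    """Replicate-level Cq wells with per-gene efficiencies.

    ``wells`` is a long-format DataFrame with columns
    (sample, group, gene, replicate, cq); ``efficiency_of`` maps gene to
    amplification efficiency in (1, 2], defaulting to 2.0 for genes left
    unmeasured; ``housekeeping_candidates`` lists reference-gene candidates.
    """

    wells: pd.DataFrame
    efficiency_of: dict[str, float] = field(default_factory=dict)
    housekeeping_candidates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in WELL_COLUMNS if c not in self.wells.columns]
        if missing:
            raise ValidationError(f"wells table missing column(s): {missing}")
        cq = self.wells["cq"].to_numpy(dtype=float)
        if len(cq) == 0:
            raise ValidationError("wells table is empty")
        if np.any(~np.isfinite(cq)) or np.any(cq <= 0):
            raise ValidationError("Cq values must be finite and > 0")
        bad_groups = set(self.wells["group"]) - {"case", "control"}
        if bad_groups:
            raise ValidationError(f"unknown group label(s): {sorted(bad_groups)}")
        for gene in self.genes:
            e = self.efficiency_of.setdefault(gene, 2.0)
            if not (1.0 < e <= 2.0):
                raise ValidationError(
                    f"efficiency for {gene!r} must be in (1, 2], got {e}"
                )

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.wells["gene"]))

    def sample_means(self, gene: str) -> pd.DataFrame:
        """Replicate-averaged Cq per sample for one gene, with group labels."""
        sub = self.wells[self.wells["gene"] == gene]
        if sub.empty:
            raise ValidationError(f"gene {gene!r} not present in wells table")
        means = sub.groupby("sample", sort=False).agg(
            cq=("cq", "mean"), group=("group", "first")
        )
        return means

    def write(self, path: str | Path) -> None:
        self.wells[WELL_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_qpcr(
    wells_path: str | Path,
    efficiency_path: str | Path | None = None,
    housekeeping: list[str] | None = None,
) -> QpcrTable:
    """Read a long-format wells TSV and optional (gene, efficiency) TSV."""
    wells = pd.read_csv(wells_path, sep="\t")
    eff: dict[str, float] = {}
    if efficiency_path is not None:
        eff_df = pd.read_csv(efficiency_path, sep="\t")
        if not {"gene", "efficiency"} <= set(eff_df.columns):
            raise ValidationError("efficiency file needs columns gene, efficiency")
        eff = dict(zip(eff_df["gene"], eff_df["efficiency"].astype(float)))
    return QpcrTable(wells, eff, list(housekeeping or []))


@dataclass
class RelativeExpressionResult:
    gene: str
    ratio: float
    p_perm: float
    n_permutations: int
    reference_gene: str

    def __post_init__(self) -> None:
        if not self.ratio > 0:
            raise ValidationError(f"ratio must be > 0, got {self.ratio}")
        if not 0 <= self.p_perm <= 1:
            raise ValidationError(f"p_perm must be in [0, 1], got {self.p_perm}")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def select_housekeeper(t: QpcrTable) -> str:
    """Candidate with the smallest sd of replicate-averaged Cq across all
    samples; ties broken by candidate input order."""
    best: str | None = None
    best_sd = math.inf
    samples = set(t.wells["sample"])
    for gene in t.housekeeping_candidates:
        sub = t.wells[t.wells["gene"] == gene]
        if set(sub["sample"]) != samples:
            continue  # incomplete data
        sd = float(sub.groupby("sample", sort=False)["cq"].mean().std(ddof=1))
        if sd < best_sd:
            best, best_sd = gene, sd
    if best is None:
        raise ValidationError("no housekeeping candidate with complete data")
    logger.info("selected housekeeping gene %s (sd=%.4g cycles)", best, best_sd)
    return best


def _ratio_from_means(
    target_cq: np.ndarray,
    ref_cq: np.ndarray,
    is_case: np.ndarray,
    e_target: float,
    e_ref: float,
) -> float:
    d_target = target_cq[~is_case].mean() - target_cq[is_case].mean()
    d_ref = ref_cq[~is_case].mean() - ref_cq[is_case].mean()
    return float(e_target**d_target / e_ref**d_ref)


def _aligned_means(t: QpcrTable, gene: str, reference: str):
    tm = t.sample_means(gene)
    rm = t.sample_means(reference)
    samples = [s for s in tm.index if s in rm.index]
    tm = tm.loc[samples]
    rm = rm.loc[samples]
    is_case = (tm["group"] == "case").to_numpy()
    if is_case.sum() == 0 or (~is_case).sum() == 0:
        raise ValidationError(
            f"gene {gene!r} vs {reference!r}: both groups must be measured"
        )
    return (
        tm["cq"].to_numpy(dtype=float),
        rm["cq"].to_numpy(dtype=float),
        is_case,
    )


def relative_ratio(t: QpcrTable, gene: str, reference: str) -> float:
    """Efficiency-corrected case/control expression ratio of ``gene``
    normalised to ``reference``."""
    target_cq, ref_cq, is_case = _aligned_means(t, gene, reference)
    return _ratio_from_means(
        target_cq, ref_cq, is_case, t.efficiency_of[gene], t.efficiency_of[reference]
    )


def randomisation_test(
    t: QpcrTable,
    gene: str,
    reference: str,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, int]:
    """Pairwise fixed reallocation randomisation test on |log2 ratio|.

    Group labels are reallocated across samples, preserving group sizes, and
    the efficiency-corrected ratio recomputed each time. When the number of
    distinct reallocations C(n, n_case) is at most ``n_perm`` the test
    enumerates them all and returns the exact p = #{|log2 r*| >= |log2 r|}/N
    (the identity reallocation is included, so p > 0). Otherwise ``n_perm``
    random reallocations are drawn and p = (1 + #{>=}) / (1 + n_perm).

    Returns (p, number of reallocations evaluated).
    """
    target_cq, ref_cq, is_case = _aligned_means(t, gene, reference)
    n = len(is_case)
    n_case = int(is_case.sum())
    if n_case < 2 or n - n_case < 2:
        raise ValidationError("each group needs at least 2 samples")
    e_t, e_r = t.efficiency_of[gene], t.efficiency_of[reference]
    obs = abs(
        math.log2(_ratio_from_means(target_cq, ref_cq, is_case, e_t, e_r))
    )
    total = math.comb(n, n_case)
    tol = 1e-12  # |log2 ratio| is a continuous statistic; guard ties at equality
    if total <= n_perm:
        count = 0
        for case_idx in combinations(range(n), n_case):
            lab = np.zeros(n, dtype=bool)
            lab[list(case_idx)] = True
            stat = abs(
                math.log2(_ratio_from_means(target_cq, ref_cq, lab, e_t, e_r))
            )
            if stat >= obs - tol:
                count += 1
        return count / total, total
    rng = rng if rng is not None else np.random.default_rng()
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        lab = np.zeros(n, dtype=bool)
        lab[perm[:n_case]] = True
        stat = abs(math.log2(_ratio_from_means(target_cq, ref_cq, lab, e_t, e_r)))
        if stat >= obs - tol:
            count += 1
    return (1 + count) / (1 + n_perm), n_perm


def analyze_qpcr(
    t: QpcrTable,
    n_perm: int = 10_000,
    seed: int = 0,
    reference: str | None = None,
) -> pd.DataFrame:
    """Relative expression + randomisation p for every non-housekeeping gene.

    The reference defaults to the most consistent housekeeping candidate.
    Returns a DataFrame with columns (gene, ratio, p_perm, n_permutations,
    reference_gene).
    """
    ref = reference if reference is not None else select_housekeeper(t)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 606]))
    rows = []
    for gene in t.genes:
        if gene == ref or gene in t.housekeeping_candidates:
            continue
        ratio = relative_ratio(t, gene, ref)
        p, n_used = randomisation_test(t, gene, ref, n_perm=n_perm, rng=rng)
        res = RelativeExpressionResult(gene, ratio, p, n_used, ref)
        rows.append(
            {
                "gene": res.gene,
                "ratio": res.ratio,
                "p_perm": res.p_perm,
                "n_permutations": res.n_permutations,
                "reference_gene": res.reference_gene,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "ratio", "p_perm", "n_permutations", "reference_gene"])
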