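"""Synthetic blastocyst-transcriptome generator with known ground truth.

Emulates a two-group (case vs control, 6 + 6 blastocysts) bulk expression
study on an RPKM-like continuous scale, with two planted headline effects:

* a configurable fraction of transcripts truly differential, most of them
  down-regulated in the case group (global downregulation), and
* an excess of differential transcripts whose gene start sites lie within a
  sub-telomeric window (default 10 Mb) of either chromosome end.

The noise model is log-normal: Gaussian on the log2 scale, exponentiated
back to a non-negative expression scale. All randomness flows through one
seeded generator per call; identical config + seed gives identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GenomeAnnotation, ValidationError

# GRCh38 primary-assembly lengths, autosomes + X (bp).
GRCH38_CHROM_LENGTHS: dict[str, int] = {
    "chr1": 248_956_422, "chr2": 242_193_529, "chr3": 198_295_559,
    "chr4": 190_214_555, "chr5": 181_538_259, "chr6": 170_805_979,
    "chr7": 159_345_973, "chr8": 145_138_636, "chr9": 138_394_717,
    "chr10": 133_797_422, "chr11": 135_086_622, "chr12": 133_275_309,
    "chr13": 114_364_328, "chr14": 107_043_718, "chr15": 101_991_189,
    "chr16": 90_338_345, "chr17": 83_257_441, "chr18": 80_373_285,
    "chr19": 58_617_616, "chr20": 64_444_167, "chr21": 46_709_983,
    "chr22": 50_818_468, "chrX": 156_040_895,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the structure of the emulated design: ~25,000
    transcripts over the GRCh38 autosomes + X, 6 samples per group, 8% of
    transcripts truly differential with 95% of those down-regulated, and a
    1.9-fold excess of differential gene starts within 10 Mb of a
    chromosome end (which puts ~28% of differential transcripts in
    sub-telomeric windows genome-wide).
    """

    n_transcripts: int = 25_000
    n_samples_per_group: int = 6
    dropout_control: bool = False
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(GRCH38_CHROM_LENGTHS)
    )
    frac_de: float = 0.08
    frac_down_among_de: float = 0.95
    effect_size_log2: float = 1.5
    telomere_window_bp: int = 10_000_000
    telomere_enrichment: float = 1.9
    enriched_chroms: Sequence[str] | None = None  # None = enrichment on every chromosome
    noise_sd_log2: float = 0.5
    baseline_logmean_range: tuple[float, float] = (-2.0, 6.0)
    frac_all_zero: float = 0.05
    frac_near_zero: float = 0.05
    seed: int = 0

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_lengths)

    def __post_init__(self) -> None:
        if not 0 <= self.frac_de <= 1:
            raise ValidationError(f"frac_de must be in [0,1], got {self.frac_de}")
        if not 0 <= self.frac_down_among_de <= 1:
            raise ValidationError(
                f"frac_down_among_de must be in [0,1], got {self.frac_down_among_de}"
            )
        if self.telomere_enrichment < 1:
            raise ValidationError(
                f"telomere_enrichment must be >= 1, got {self.telomere_enrichment}"
            )
        if self.frac_all_zero + self.frac_near_zero + self.frac_de > 1:
            raise ValidationError(
                "frac_all_zero + frac_near_zero + frac_de exceeds 1"
            )
        if self.n_samples_per_group < 2:
            raise ValidationError("n_samples_per_group must be >= 2")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValidationError(
                    f"chromosome {chrom!r} has non-positive length {length}"
                )
        if self.enriched_chroms is not None:
            unknown = set(self.enriched_chroms) - set(self.chrom_lengths)
            if unknown:
                raise ValidationError(f"enriched_chroms not in genome: {sorted(unknown)}")
        lo, hi = self.baseline_logmean_range
        if not lo < hi:
            raise ValidationError("baseline_logmean_range must be an increasing interval")


@dataclass
class GroundTruth:
    """Planted truth: which transcripts are differential, their direction, and
    whether their gene start lies in a sub-telomeric window."""

    de_transcript_ids: set[str]
    direction_by_id: dict[str, str]  # id -> "down" | "up"
    telomeric_by_id: dict[str, bool]

    def __post_init__(self) -> None:
        if set(self.direction_by_id) != self.de_transcript_ids:
            raise ValidationError("direction_by_id keys must equal de_transcript_ids")


def _transcript_ids(n: int) -> list[str]:
    width = max(6, len(str(n)))
    return [f"T{i:0{width}d}" for i in range(n)]


def _designate(cfg: SimulationConfig) -> dict:
    """Deterministic partition of transcripts into all-zero / near-zero /
    differential / null sets, with directions for the differential set.

    Shared by the annotation and expression generators so both see the same
    ground truth for a given config + seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 101]))
    ids = _transcript_ids(cfg.n_transcripts)
    order = rng.permutation(cfg.n_transcripts)
    n_zero = int(round(cfg.frac_all_zero * cfg.n_transcripts))
    n_near = int(round(cfg.frac_near_zero * cfg.n_transcripts))
    n_de = int(round(cfg.frac_de * cfg.n_transcripts))
    zero_idx = order[:n_zero]
    near_idx = order[n_zero : n_zero + n_near]
    de_idx = order[n_zero + n_near : n_zero + n_near + n_de]
    n_down = int(round(cfg.frac_down_among_de * n_de))
    directions = np.array(["up"] * n_de, dtype=object)
    directions[:n_down] = "down"
    rng.shuffle(directions)
    return {
        "ids": ids,
        "zero_ids": {ids[i] for i in zero_idx},
        "near_zero_ids": {ids[i] for i in near_idx},
        "de_ids": [ids[i] for i in de_idx],
        "direction_by_id": {ids[i]: d for i, d in zip(de_idx, directions)},
    }


def _window_fraction(length: int, window: int) -> float:
    """Fraction of a chromosome covered by the two telomeric windows
    (truncated to non-overlapping halves on short chromosomes)."""
    return min(2 * window, length) / length


def simulate_annotation(cfg: SimulationConfig) -> GenomeAnnotation:
    """Assign every transcript a chromosome and gene start position.

    Chromosomes are drawn with probability proportional to length and starts
    uniformly on ``[0, L)``. Transcripts pre-designated as differential draw
    their start from a two-component mixture (uniform genome-wide vs uniform
    within the two telomeric windows) whose weight is set so that the
    probability of landing in a window is
    ``min(telomere_enrichment * f, 1)`` where ``f`` is the windows' length
    fraction of the chromosome — an invertible planting that recovery tests
    can check against. With ``telomere_enrichment = 1`` the differential and
    non-differential position laws coincide.
    """
    des = _designate(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 202]))
    chroms = list(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    n = cfg.n_transcripts
    ids = des["ids"]
    chrom_idx = rng.choice(len(chroms), size=n, p=probs)
    starts = np.floor(rng.random(n) * lengths[chrom_idx]).astype(np.int64)

    de_set = set(des["de_ids"])
    enriched = (
        set(cfg.chrom_lengths) if cfg.enriched_chroms is None else set(cfg.enriched_chroms)
    )
    w = cfg.telomere_window_bp
    for i, tid in enumerate(ids):
        if tid not in de_set:
            continue
        chrom = chroms[chrom_idx[i]]
        if chrom not in enriched:
            continue
        L = cfg.chrom_lengths[chrom]
        f = _window_fraction(L, w)
        target = min(cfg.telomere_enrichment * f, 1.0)
        mix = 0.0 if f >= 1 else (target - f) / (1 - f)
        if rng.random() < mix:
            # uniform within the two (possibly truncated) windows
            half = min(w, L // 2)
            u = rng.random() * 2 * half
            starts[i] = int(u) if u < half else int(L - 2 * half + u)
            starts[i] = min(starts[i], L - 1)

    gene_start_of = {
        tid: (chroms[chrom_idx[i]], int(starts[i])) for i, tid in enumerate(ids)
    }
    return GenomeAnnotation(dict(cfg.chrom_lengths), gene_start_of)


def simulate_expression(
    cfg: SimulationConfig, ann: GenomeAnnotation
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate the expression matrix and return it with the planted truth.

    Per-transcript baseline log2 means are uniform on
    ``baseline_logmean_range``; differential transcripts draw from the upper
    70% of that range so the low-expression filters cannot remove planted
    truth. Case-group means are shifted by ``±effect_size_log2`` according to
    the planted direction; i.i.d. Gaussian noise of sd ``noise_sd_log2`` is
    added on the log2 scale and values are exponentiated back. A fraction of
    transcripts is set all-zero and another near-zero (mean < 0.05) to give
    the filtering rules work to do.
    """
    if set(_transcript_ids(cfg.n_transcripts)) - set(ann.gene_start_of):
        raise ValidationError("annotation does not cover all configured transcripts")
    des = _designate(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 303]))
    ids = des["ids"]
    n = cfg.n_transcripts
    k = cfg.n_samples_per_group
    case_samples = [f"AMA{i + 1}" for i in range(k)]
    control_samples = [f"DC{i + 1}" for i in range(k)]
    samples = case_samples + control_samples

    lo, hi = cfg.baseline_logmean_range
    baseline = rng.uniform(lo, hi, size=n)
    de_ids = des["de_ids"]
    de_pos = {tid: i for i, tid in enumerate(ids)}
    de_rows = np.array([de_pos[t] for t in de_ids], dtype=int)
    if len(de_rows):
        baseline[de_rows] = rng.uniform(lo + 0.3 * (hi - lo), hi, size=len(de_rows))

    shift = np.zeros(n)
    for tid in de_ids:
        sgn = -1.0 if des["direction_by_id"][tid] == "down" else 1.0
        shift[de_pos[tid]] = sgn * cfg.effect_size_log2

    mean_log2 = np.tile(baseline[:, None], (1, 2 * k)).astype(float)
    mean_log2[:, :k] += shift[:, None]
    log2_vals = mean_log2 + rng.normal(0.0, cfg.noise_sd_log2, size=(n, 2 * k))
    values = np.power(2.0, log2_vals)

    zero_rows = np.array([de_pos[t] for t in des["zero_ids"]], dtype=int)
    near_rows = np.array([de_pos[t] for t in des["near_zero_ids"]], dtype=int)
    if len(zero_rows):
        values[zero_rows, :] = 0.0
    if len(near_rows):
        values[near_rows, :] = rng.uniform(0.0, 0.04, size=(len(near_rows), 2 * k))

    df = pd.DataFrame(values, index=ids, columns=samples)
    group_of = {s: "case" for s in case_samples}
    group_of.update({s: "control" for s in control_samples})
    if cfg.dropout_control:
        dropped = control_samples[-1]
        df = df.drop(columns=[dropped])
        del group_of[dropped]

    w = cfg.telomere_window_bp
    telomeric = {}
    for tid in ids:
        chrom, pos = ann.gene_start_of[tid]
        L = ann.chrom_lengths[chrom]
        telomeric[tid] = pos <= w or pos >= L - w
    truth = GroundTruth(
        de_transcript_ids=set(de_ids),
        direction_by_id=dict(des["direction_by_id"]),
        telomeric_by_id=telomeric,
    )
    return ExpressionMatrix(df, group_of), truth


def write_ground_truth(truth: GroundTruth, path) -> None:
    rows = [
        {
            "transcript_id": tid,
            "direction": truth.direction_by_id[tid],
            "telomeric": truth.telomeric_by_id.get(tid, False),
        }
        for tid in sorted(truth.de_transcript_ids)
    ]
    pd.DataFrame(rows, columns=["transcript_id", "direction", "telomeric"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# qPCR table simulation
# ---------------------------------------------------------------------------


def simulate_qpcr(
    n_per_group: int,
    genes: Sequence[str],
    housekeeping: Sequence[str],
    planted_log2_ratio: Mapping[str, float],
    efficiency: Mapping[str, float] | None = None,
    cq_noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 2,
):
    """Simulate a replicate-level Cq table for a two-group validation run.

    Every sample is run in ``n_replicates`` wells per gene. The case group's
    mean Cq for gene g is shifted by ``-planted_log2_ratio[g] / log2(E_g)``
    cycles relative to a per-gene baseline, so the downstream
    efficiency-corrected ratio recovers ``2**planted_log2_ratio`` exactly in
    the noiseless case. Housekeeping genes must have planted ratio 0.
    """
    from .qpcr import QpcrTable  # local import to avoid a cycle

    efficiency = dict(efficiency or {})
    for g in list(genes) + list(housekeeping):
        efficiency.setdefault(g, 2.0)
    for g, e in efficiency.items():
        if not (1.0 < e <= 2.0):
            raise ValidationError(f"efficiency for {g!r} must be in (1, 2], got {e}")
    for g in housekeeping:
        if planted_log2_ratio.get(g, 0.0) != 0.0:
            raise ValidationError(f"housekeeping gene {g!r} must have planted ratio 0")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 404]))
    all_genes = list(dict.fromkeys(list(genes) + list(housekeeping)))
    baseline = {g: rng.uniform(18.0, 28.0) for g in all_genes}
    rows = []
    for group, prefix in (("case", "AMA"), ("control", "DC")):
        for s in range(n_per_group):
            sample = f"{prefix}{s + 1}"
            for g in all_genes:
                shift = planted_log2_ratio.get(g, 0.0) if group == "case" else 0.0
                mu = baseline[g] - shift / np.log2(efficiency[g])
                for rep in range(n_replicates):
                    cq = mu + rng.normal(0.0, cq_noise_sd) if cq_noise_sd > 0 else mu
                    rows.append(
                        {
                            "sample": sample,
                            "group": group,
                            "gene": g,
                            "replicate": rep + 1,
                            "cq": float(cq),
                        }
                    )
    wells = pd.DataFrame(rows)
    return QpcrTable(
        wells=wells,
        efficiency_of=efficiency,
        housekeeping_candidates=list(housekeeping),
    )
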