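"""Synthetic tumor-cohort generator.

Every downstream stage of the screen is testable without any external
download: this module plants the exact statistical structure the analysis
assumes and returns the ground truth alongside the data —

* a negative-binomial miRNA count matrix in which both arms of a chosen set
  of precursor duplexes are up-regulated in tumors by a known log2 effect;
* a gene expression matrix whose true-target genes are down-shifted in
  tumors and negatively coupled to a driver miRNA through a shared latent
  variable;
* a clinical table whose event times follow an exponential
  proportional-hazards model in which below-median expression of the
  prognostic genes multiplies the hazard, with independent uniform
  censoring and independent stage/grade/age covariates;
* 3'-UTR sequences with seed sites planted at recorded positions on a
  background scrubbed of accidental matches to the driver's own patterns.

All generators are deterministic given ``SimConfig.seed``; each draws from
its own stream (seeded from the config seed plus a fixed per-operation
offset) so adding one generator never perturbs another's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ClinicalTable, CountMatrix, SequenceRecord
from .seed_sites import seed_patterns
from .signature import MatureMiRNA

# stream offsets: one per generator
_STREAM_COUNTS = 1
_STREAM_EXPRESSION = 2
_STREAM_SURVIVAL = 3
_STREAM_UTR = 4

#: mature miR-31 duplex sequences (miRBase), the study's driver duplex
MIR31_5P = "AGGCAAGATGCTGGCATAGCT"
MIR31_3P = "TGCTATGCCAACATATTGCCAT"


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults mirror the study conditions: a clinical cohort of 518 tumors
    and 44 normals, seven precursor duplexes planted up-regulated above the
    1.5 log2FC call threshold, target genes shifted below the -2.0 down cut,
    and below-median expression of prognostic genes carrying a hazard ratio
    large enough to be a genuine prognostic signal at this cohort size.
    """

    n_tumor: int = 518
    n_normal: int = 44
    n_mirnas: int = 200
    n_duplex_up: int = 7
    planted_log2fc: float = 2.5
    nb_dispersion: float = 0.2
    n_genes: int = 400
    n_true_targets: int = 20
    target_log2fc: float = -2.8
    corr_strength: float = 0.5
    baseline_hazard: float = 0.012  # events per month
    hr_low_expression: float = 2.5
    censor_horizon: float = 120.0  # months
    utr_length: int = 2000
    sites_per_target: Mapping[str, int] = field(
        default_factory=lambda: {"8mer": 1, "7mer-A1": 1}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tumor", "n_normal", "n_mirnas", "n_duplex_up", "n_genes", "n_true_targets"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.corr_strength <= 1.0:
            raise ValueError("corr_strength must be in [0, 1]")
        if self.hr_low_expression <= 0:
            raise ValueError("hr_low_expression must be > 0")
        if self.censor_horizon <= 0:
            raise ValueError("censor_horizon must be > 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")


@dataclass
class GroundTruth:
    """What was planted, so recovery can be scored exactly."""

    up_mirnas: set[str] = field(default_factory=set)
    duplex_precursors: set[str] = field(default_factory=set)
    true_targets: set[str] = field(default_factory=set)
    planted_sites: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    prognostic_genes: set[str] = field(default_factory=set)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            self.up_mirnas | other.up_mirnas,
            self.duplex_precursors | other.duplex_precursors,
            self.true_targets | other.true_targets,
            {**self.planted_sites, **other.planted_sites},
            self.prognostic_genes | other.prognostic_genes,
        )


def _rng(cfg: SimConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, offset])


def _sample_ids(cfg: SimConfig) -> tuple[list[str], dict[str, str]]:
    tumors = [f"T{i + 1:04d}" for i in range(cfg.n_tumor)]
    normals = [f"N{i + 1:04d}" for i in range(cfg.n_normal)]
    groups = {s: "tumor" for s in tumors} | {s: "normal" for s in normals}
    return tumors + normals, groups


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with variance mu + mu^2 * dispersion (Poisson when dispersion=0)."""
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


# ---------------------------------------------------------------------------
# miRNA counts
# ---------------------------------------------------------------------------


def simulate_mirna_counts(cfg: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """NB count matrix with both arms of ``n_duplex_up`` precursors planted up.

    Features are mature names ``sim-mir-<k>-5p`` / ``-3p``; the first
    ``n_duplex_up`` precursors have tumor mean = normal mean x
    2^planted_log2fc on BOTH arms, the rest are null.
    """
    if cfg.n_duplex_up * 2 > cfg.n_mirnas:
        raise ValueError("n_duplex_up * 2 exceeds n_mirnas")
    rng = _rng(cfg, _STREAM_COUNTS)
    n_prec = (cfg.n_mirnas + 1) // 2
    features: list[str] = []
    for k in range(n_prec):
        features.append(f"sim-mir-{k + 1:03d}-5p")
        if len(features) < cfg.n_mirnas:
            features.append(f"sim-mir-{k + 1:03d}-3p")
    features = features[: cfg.n_mirnas]
    sample_ids, groups = _sample_ids(cfg)
    is_tumor = np.array([groups[s] == "tumor" for s in sample_ids])

    base_mean = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=cfg.n_mirnas)
    planted = features[: cfg.n_duplex_up * 2]
    fold = np.ones(cfg.n_mirnas)
    fold[: cfg.n_duplex_up * 2] = 2.0**cfg.planted_log2fc
    mean_matrix = base_mean[:, None] * np.where(is_tumor[None, :], fold[:, None], 1.0)
    counts = _nb_draw(rng, mean_matrix, cfg.nb_dispersion)

    truth = GroundTruth(
        up_mirnas=set(planted),
        duplex_precursors={f"sim-mir-{k + 1:03d}" for k in range(cfg.n_duplex_up)},
    )
    matrix = CountMatrix(features, sample_ids, counts.astype(float), groups)
    return matrix, truth


# ---------------------------------------------------------------------------
# gene expression
# ---------------------------------------------------------------------------


def gene_ids(cfg: SimConfig) -> list[str]:
    return [f"GENE{i + 1:04d}" for i in range(cfg.n_genes)]


def true_target_ids(cfg: SimConfig) -> list[str]:
    return gene_ids(cfg)[: cfg.n_true_targets]


def simulate_gene_expression(
    cfg: SimConfig, driver_mirna_levels: pd.Series
) -> tuple[pd.DataFrame, GroundTruth]:
    """Gene expression (linear scale, genes x samples) coupled to a driver.

    True targets are generated on the log2 scale as
    baseline - corr_strength * standardized(driver) + noise, plus a tumor
    shift of ``target_log2fc``; non-targets are independent of the driver.
    Sample names (and tumor/normal status, via the T/N prefix convention of
    :func:`simulate_mirna_counts`) come from ``driver_mirna_levels``'s index.
    """
    if cfg.n_true_targets > cfg.n_genes:
        raise ValueError("n_true_targets exceeds n_genes")
    rng = _rng(cfg, _STREAM_EXPRESSION)
    samples = list(driver_mirna_levels.index)
    driver = driver_mirna_levels.to_numpy(dtype=float)
    if np.ptp(driver) == 0:
        raise ValueError("driver levels are constant; cannot standardize")
    z = (driver - driver.mean()) / driver.std()
    is_tumor = np.array([s.startswith("T") for s in samples])

    genes = gene_ids(cfg)
    targets = set(true_target_ids(cfg))
    baseline = rng.normal(8.0, 1.0, size=cfg.n_genes)  # log2 abundance
    noise_sd = 0.5
    log2 = np.empty((cfg.n_genes, len(samples)))
    for i, g in enumerate(genes):
        eps = rng.normal(0.0, noise_sd, size=len(samples))
        row = baseline[i] + eps
        if g in targets:
            row = row - cfg.corr_strength * z + cfg.target_log2fc * is_tumor
        log2[i] = row
    expr = pd.DataFrame(2.0**log2, index=genes, columns=samples)
    truth = GroundTruth(true_targets=targets)
    return expr, truth


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def simulate_survival(
    expr: pd.DataFrame,
    cfg: SimConfig,
    prognostic_genes: Sequence[str] | None = None,
) -> tuple[ClinicalTable, GroundTruth]:
    """Clinical table with expression-dependent exponential hazards.

    ``expr`` is genes x patients (tumor cohort). For each prognostic gene,
    patients whose expression is below the cohort median have their hazard
    multiplied by ``hr_low_expression``; effects of multiple prognostic
    genes are multiplicative. Censoring is independent uniform on
    (0, censor_horizon]. Stage (ordinal 1-4), grade (1-3) and age
    (normal(60,10) truncated to [18, 90]) are drawn independently of the
    hazard; they exist to exercise the multivariate adjustment.
    """
    if expr.shape[1] == 0:
        raise ValueError("empty cohort")
    rng = _rng(cfg, _STREAM_SURVIVAL)
    patients = list(expr.columns)
    n = len(patients)
    if prognostic_genes is None:
        prognostic_genes = [g for g in expr.index]
    missing = [g for g in prognostic_genes if g not in expr.index]
    if missing:
        raise ValueError(f"prognostic genes absent from expression: {missing}")

    log_hazard = np.full(n, np.log(cfg.baseline_hazard))
    for g in prognostic_genes:
        v = expr.loc[g].to_numpy(dtype=float)
        low = v <= np.median(v)
        log_hazard += np.log(cfg.hr_low_expression) * low
    hazard = np.exp(log_hazard)

    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, cfg.censor_horizon, size=n)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    time = np.maximum(time, 1e-6)  # ClinicalTable requires strictly positive

    stage = rng.integers(1, 5, size=n)
    grade = rng.integers(1, 4, size=n)
    age = np.clip(rng.normal(60.0, 10.0, size=n), 18.0, 90.0)

    df = pd.DataFrame(
        {
            "patient_id": patients,
            "time": time,
            "event": event,
            "stage": stage,
            "grade": grade,
            "age": age,
        }
    )
    expr_cols = pd.DataFrame(expr.to_numpy(dtype=float).T, columns=list(expr.index))
    df = pd.concat([df, expr_cols], axis=1)
    table = ClinicalTable(df, expression_columns=list(expr.index))
    truth = GroundTruth(prognostic_genes=set(prognostic_genes))
    return table, truth


# ---------------------------------------------------------------------------
# UTRs with planted sites
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _scrub(seq: list[str], patterns: Sequence[str], protected: list[tuple[int, int]],
           rng: np.random.Generator, max_rounds: int = 500) -> None:
    """Resample accidental pattern occurrences outside protected intervals.

    An occurrence lying entirely inside a protected (planted-site) interval
    is legitimate — it is the planted site itself or one of its embedded
    sub-patterns, which the scanner's suppression rule accounts for. Any
    other occurrence has its unprotected bases redrawn; rounds repeat until
    a full scan is clean.
    """
    for _ in range(max_rounds):
        s = "".join(seq)
        dirty = False
        for pat in patterns:
            start = s.find(pat)
            while start != -1:
                end = start + len(pat)
                if not any(ps <= start and end <= pe for ps, pe in protected):
                    for i in range(start, end):
                        if not any(ps <= i < pe for ps, pe in protected):
                            seq[i] = str(rng.choice(_BASES))
                    dirty = True
                start = s.find(pat, start + 1)
        if not dirty:
            return
    raise RuntimeError("could not scrub accidental seed matches")


def simulate_utrs(
    cfg: SimConfig,
    mirna: MatureMiRNA,
    target_genes: Sequence[str] | None = None,
    all_genes: Sequence[str] | None = None,
    extra_clean_patterns: Sequence[str] = (),
    stream_offset: int = _STREAM_UTR,
) -> tuple[list[SequenceRecord], GroundTruth]:
    """UTR FASTA records with exact planted sites for one miRNA.

    Background bases are i.i.d. uniform; any accidental occurrence of the
    driver's own site patterns (plus ``extra_clean_patterns``) is removed by
    rejection-resampling of the colliding window, so the planted truth is
    exact for the tested miRNA. ``cfg.sites_per_target`` sites are planted
    per target gene at recorded, non-overlapping positions.
    """
    if mirna.sequence is None:
        raise ValueError("mirna needs a sequence")
    patterns = seed_patterns(mirna.sequence.sequence)
    wanted = {t: int(k) for t, k in cfg.sites_per_target.items() if k}
    unknown = set(wanted) - set(patterns)
    if unknown:
        raise ValueError(f"unknown site types requested: {sorted(unknown)}")
    longest = max((len(patterns[t]) for t in wanted), default=0)
    if cfg.utr_length < longest:
        raise ValueError("utr_length shorter than the longest planted pattern")

    genes = list(all_genes) if all_genes is not None else gene_ids(cfg)
    targets = list(target_genes) if target_genes is not None else true_target_ids(cfg)
    missing = [g for g in targets if g not in genes]
    if missing:
        raise ValueError(f"target genes not in gene set: {missing}")

    total_span = sum(k * (len(patterns[t]) + 1) for t, k in wanted.items())
    if total_span > cfg.utr_length:
        raise ValueError("requested sites do not fit in utr_length without overlap")

    rng = _rng(cfg, stream_offset)
    clean_patterns = list(dict.fromkeys(list(patterns.values()) + list(extra_clean_patterns)))
    records: list[SequenceRecord] = []
    truth = GroundTruth()
    target_set = set(targets)
    for g in genes:
        seq = list(rng.choice(_BASES, size=cfg.utr_length))
        planted: list[tuple[int, str]] = []
        protected: list[tuple[int, int]] = []
        if g in target_set and wanted:
            placements: list[tuple[str, str]] = []
            for t in sorted(wanted):
                placements += [(t, patterns[t])] * wanted[t]
            positions = _place_sites(rng, cfg.utr_length, [len(p) for _, p in placements])
            for (t, pat), pos in zip(placements, positions):
                seq[pos : pos + len(pat)] = list(pat)
                planted.append((pos, t))
                protected.append((pos, pos + len(pat)))
            planted.sort()
        _scrub(seq, clean_patterns, protected, rng)
        records.append(SequenceRecord(g, "synthetic 3'UTR", "".join(seq)))
        if planted:
            truth.planted_sites[g] = planted
            truth.true_targets.add(g)
    return records, truth


def _place_sites(
    rng: np.random.Generator, length: int, sizes: list[int], max_tries: int = 1000
) -> list[int]:
    """Non-overlapping random starts (separated by >= 1 base) for the sizes."""
    for _ in range(max_tries):
        placed: list[tuple[int, int]] = []
        assigned: list[int] = []
        ok = True
        for s in sizes:
            st = int(rng.integers(0, length - s + 1))
            if any(st < b + 1 and a < st + s + 1 for a, b in placed):
                ok = False
                break
            placed.append((st, st + s))
            assigned.append(st)
        if ok:
            return assigned
    raise ValueError("requested sites overlap; cannot place without collision")


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------


@dataclass
class SyntheticBundle:
    """Everything the end-to-end screen consumes, plus the planted truth."""

    counts: CountMatrix
    mirna_records: list[SequenceRecord]
    expression: pd.DataFrame
    utrs: list[SequenceRecord]
    clinical: ClinicalTable
    truth: GroundTruth
    config: SimConfig


def simulate_bundle(
    cfg: SimConfig,
    n_prognostic: int = 5,
    fraction_5p_targets: float = 0.25,
) -> SyntheticBundle:
    """Generate a coherent cohort for the whole pipeline.

    The planted driver duplex is miR-31: its mature sequences replace the
    first simulated precursor's arms so seed-site prediction has real
    patterns to work with. True targets are split between the arms
    (``fraction_5p_targets`` to 5p, mirroring the screen's arm imbalance);
    the first ``n_prognostic`` targets also carry the survival signal.
    """
    counts, truth_counts = simulate_mirna_counts(cfg)
    driver_5p = MatureMiRNA("hsa-miR-31-5p", "hsa-miR-31", "5p",
                            SequenceRecord("hsa-miR-31-5p", "", MIR31_5P))
    driver_3p = MatureMiRNA("hsa-miR-31-3p", "hsa-miR-31", "3p",
                            SequenceRecord("hsa-miR-31-3p", "", MIR31_3P))
    # rename the first planted duplex to the real driver
    rename = {"sim-mir-001-5p": "hsa-miR-31-5p", "sim-mir-001-3p": "hsa-miR-31-3p"}
    counts.feature_ids = [rename.get(f, f) for f in counts.feature_ids]
    truth = GroundTruth(
        up_mirnas={rename.get(f, f) for f in truth_counts.up_mirnas},
        duplex_precursors={
            "hsa-miR-31" if p == "sim-mir-001" else p for p in truth_counts.duplex_precursors
        },
    )

    # driver levels: CPM of the 3p arm (the arm with most targets in the study)
    from .signature import normalize_cpm  # local import to avoid cycle at module load

    cpm = normalize_cpm(counts)
    driver_levels = cpm.loc["hsa-miR-31-3p"]

    expr, truth_expr = simulate_gene_expression(cfg, driver_levels)
    truth = truth.merge(truth_expr)

    targets = true_target_ids(cfg)
    n5 = int(round(len(targets) * fraction_5p_targets))
    targets_5p, targets_3p = targets[:n5], targets[n5:]
    pat5 = list(seed_patterns(MIR31_5P).values())
    pat3 = list(seed_patterns(MIR31_3P).values())
    utrs5, truth_u5 = simulate_utrs(
        cfg, driver_5p, target_genes=targets_5p, all_genes=gene_ids(cfg)[: len(targets_5p)],
        extra_clean_patterns=pat3, stream_offset=_STREAM_UTR,
    )
    utrs3, truth_u3 = simulate_utrs(
        cfg, driver_3p, target_genes=targets_3p, all_genes=gene_ids(cfg)[len(targets_5p):],
        extra_clean_patterns=pat5, stream_offset=_STREAM_UTR + 10,
    )
    utrs = utrs5 + utrs3
    truth = truth.merge(truth_u5).merge(truth_u3)
    truth.true_targets = set(targets)

    tumor_cols = [s for s in expr.columns if s.startswith("T")]
    prognostic = targets[:n_prognostic]
    clinical, truth_surv = simulate_survival(expr[tumor_cols], cfg, prognostic)
    truth = truth.merge(truth_surv)

    return SyntheticBundle(
        counts=counts,
        mirna_records=[driver_5p.sequence, driver_3p.sequence],
        expression=expr,
        utrs=utrs,
        clinical=clinical,
        truth=truth,
        config=cfg,
    )
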