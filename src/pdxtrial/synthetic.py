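"""Synthetic inputs with known ground truth for every pipeline stage.

The trial this package analyzes deposited no raw animal or sequencing
data, so each consumer (growth response, read disambiguation, variant
cascade, expression binning/DE) is exercised on generated data whose
truth labels are stored alongside. The growth generator emulates the
1x1x1 design: per model three mice carry exponentially growing
xenografts, the first to reach the 50-100 mm^3 inclusion window receives
drug, the second vehicle, the third is excluded; treated growth uses a
rate reduced by a model-specific treatment effect drawn from a
three-component mixture targeting the progression / suppression /
regression classes. All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .growth import (PROGRESSION, REGRESSION, SUPPRESSION, classify_response,
                     round_half_away)
from .variants import (ANNOTATION_FIELDS, CASCADE_RULES, RETAINED,
                       RULE_DBSNP, RULE_HOMOPOLYMER, RULE_ONCOGENE,
                       RULE_POPULATION, RULE_READ_END, RULE_REGION,
                       RULE_ROLE, RULE_SYNONYMOUS, AnnotatedVariant)

#: Thrice-weekly caliper schedule over an 18-day treatment window.
DEFAULT_MEASUREMENT_DAYS = (0, 2, 4, 7, 9, 11, 14, 16, 18)


# ---------------------------------------------------------------------------
# growth cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Design constants of a simulated PDX cohort.

    The treatment-effect mixture has one component per intended response
    class. Progression and suppression components draw a target T/C
    uniformly inside their class band and invert the T/C formula for the
    treated growth rate; the regression component draws the fraction of
    baseline volume the treated tumor shrinks to by the horizon. Weights
    are converted to exact per-class model counts by largest remainder,
    so weights w with w*n integral give exactly those class sizes.
    """

    n_models: int = 31
    seed: int = 0
    baseline_volume_range: tuple[float, float] = (50.0, 100.0)
    #: log-normal parameters of the per-day exponential growth rate g;
    #: median ln(2)/4 means a four-day vehicle doubling time, typical for
    #: serially passaged melanoma xenografts in NOG mice.
    growth_rate_mu: float = math.log(math.log(2.0) / 4.0)
    growth_rate_sigma: float = 0.25
    #: (progression, suppression, regression) component weights.
    mixture_weights: tuple[float, float, float] = (10 / 31, 13 / 31, 8 / 31)
    #: target T/C bands (percent) for progression and suppression, and the
    #: final/baseline volume-fraction band for regression; band edges sit
    #: clear of the 0 and 50 class boundaries so caliper noise does not
    #: flip the intended class.
    progression_tc_band: tuple[float, float] = (70.0, 145.0)
    suppression_tc_band: tuple[float, float] = (13.0, 38.0)
    regression_shrink_band: tuple[float, float] = (0.25, 0.75)
    measurement_days: tuple[int, ...] = DEFAULT_MEASUREMENT_DAYS
    horizon: int = 18
    #: coefficient of variation of multiplicative caliper noise on each
    #: diameter (0.03 ~ sub-millimeter error on a 1 cm tumor).
    noise_cv: float = 0.03
    #: longer/shorter diameter ratio used to invert volumes to diameters.
    aspect_ratio: float = 1.3
    #: share the treated and vehicle baseline volume within a model
    #: (useful for analytic checks; the default draws them independently).
    shared_baseline: bool = False

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("need at least one model")
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if any(w < 0 for w in self.mixture_weights):
            raise ValueError("negative mixture weight")
        if not all(map(math.isfinite,
                       (self.growth_rate_mu, self.growth_rate_sigma))):
            raise ValueError("growth-rate parameters must be finite")
        if self.horizon < max(self.measurement_days):
            raise ValueError("horizon before the last measurement day")
        if self.noise_cv < 0:
            raise ValueError("negative noise CV")
        if self.aspect_ratio < 1:
            raise ValueError("aspect ratio is longer/shorter, must be >= 1")
        lo, hi = self.baseline_volume_range
        if not (0 < lo <= hi):
            raise ValueError("invalid baseline volume range")


def volume_to_diameters(volume: float, aspect_ratio: float) -> tuple[float, float]:
    """Invert ``V = shorter^2 * longer / 2`` at a fixed longer/shorter
    ratio r: shorter = (2V/r)^(1/3)."""
    shorter = (2.0 * volume / aspect_ratio) ** (1.0 / 3.0)
    return shorter, aspect_ratio * shorter


def _largest_remainder_counts(weights: Sequence[float], n: int) -> list[int]:
    raw = [w * n for w in weights]
    counts = [int(math.floor(x)) for x in raw]
    rem = n - sum(counts)
    order = sorted(range(len(weights)), key=lambda i: raw[i] - counts[i],
                   reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


def _treated_rate_for_target_tc(tc_percent: float, g: float, v0_t: float,
                                v0_c: float, horizon: int) -> float:
    """Solve 100*(T_i-T_0)/(C_i-C_0) = tc for the treated rate under
    exponential growth from the two baselines."""
    growth_c = v0_c * (math.exp(g * horizon) - 1.0)
    arg = 1.0 + (tc_percent / 100.0) * growth_c / v0_t
    if arg <= 0:
        raise ValueError("target T/C not reachable with positive volumes")
    return math.log(arg) / horizon


def gen_growth_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a caliper-measurement table and its ground truth.

    Returns ``(measurements, truth)``. Measurements have one row per
    mouse per day with the two noisy diameters; truth has one row per
    model with the vehicle growth rate ``g``, the treated rate, the
    treatment effect on g, the analytic (noise-free) T/C and the intended
    response class.
    """
    rng = np.random.default_rng(spec.seed)
    counts = _largest_remainder_counts(spec.mixture_weights, spec.n_models)
    components = ([PROGRESSION] * counts[0] + [SUPPRESSION] * counts[1]
                  + [REGRESSION] * counts[2])
    rng.shuffle(components)

    lo, hi = spec.baseline_volume_range
    sigma = math.sqrt(math.log(1.0 + spec.noise_cv ** 2))
    meas_rows, truth_rows = [], []
    for m, component in enumerate(components):
        model_id = f"M{m:03d}"
        g = float(np.exp(rng.normal(spec.growth_rate_mu,
                                    spec.growth_rate_sigma)))
        # implant volumes decide which mouse reaches the inclusion window
        # first (ties broken toward the lower mouse index)
        implants = rng.uniform(5.0, 45.0, size=3)
        entry_order = sorted(range(3), key=lambda i: (-implants[i], i))
        arms = {entry_order[0]: "treated", entry_order[1]: "vehicle",
                entry_order[2]: "excluded"}
        v0 = dict.fromkeys(range(3))
        v0[entry_order[0]] = float(rng.uniform(lo, hi))
        v0[entry_order[1]] = (v0[entry_order[0]] if spec.shared_baseline
                              else float(rng.uniform(lo, hi)))
        v0[entry_order[2]] = float(rng.uniform(lo, hi))

        v0_t = v0[entry_order[0]]
        v0_c = v0[entry_order[1]]
        if component == PROGRESSION:
            tc_target = float(rng.uniform(*spec.progression_tc_band))
            g_treated = _treated_rate_for_target_tc(
                tc_target, g, v0_t, v0_c, spec.horizon)
        elif component == SUPPRESSION:
            tc_target = float(rng.uniform(*spec.suppression_tc_band))
            g_treated = _treated_rate_for_target_tc(
                tc_target, g, v0_t, v0_c, spec.horizon)
        else:
            shrink = float(rng.uniform(*spec.regression_shrink_band))
            g_treated = math.log(shrink) / spec.horizon

        tc_analytic = (100.0
                       * v0_t * (math.exp(g_treated * spec.horizon) - 1.0)
                       / (v0_c * (math.exp(g * spec.horizon) - 1.0)))
        intended = classify_response(tc_analytic)

        for mouse in range(3):
            arm = arms[mouse]
            rate = g_treated if arm == "treated" else g
            for day in spec.measurement_days:
                vol = v0[mouse] * math.exp(rate * day)
                shorter, longer = volume_to_diameters(vol, spec.aspect_ratio)
                if spec.noise_cv > 0:
                    shorter *= float(np.exp(rng.normal(0.0, sigma)))
                    longer *= float(np.exp(rng.normal(0.0, sigma)))
                    shorter, longer = sorted((shorter, longer))
                meas_rows.append({
                    "model_id": model_id, "mouse_id": f"{model_id}_m{mouse}",
                    "arm": arm, "day": day,
                    "shorter_mm": shorter, "longer_mm": longer})
        truth_rows.append({
            "model_id": model_id, "component": component,
            "g": g, "g_treated": g_treated, "effect": g - g_treated,
            "v0_treated": v0_t, "v0_vehicle": v0_c,
            "tc_analytic": tc_analytic, "true_class": intended})

    measurements = pd.DataFrame(meas_rows)
    truth = pd.DataFrame(truth_rows)
    return measurements, truth


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadSimSpec:
    n_reads: int = 10_000
    fraction_human: float = 0.7
    fraction_mouse: float = 0.1
    fraction_ambiguous: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.fraction_human + self.fraction_mouse + self.fraction_ambiguous
        if abs(total - 1.0) > 1e-9:
            raise ValueError("read fractions must sum to 1")
        if self.n_reads < 0:
            raise ValueError("negative read count")


def gen_reads(spec: ReadSimSpec) -> pd.DataFrame:
    """Per-read mapping flags with a ``truth`` species label.

    Human reads map human-only with a human primary; mouse reads map
    mouse-only; ambiguous reads map to both with the primary alignment
    assigned to human by a fair Bernoulli draw.
    """
    rng = np.random.default_rng(spec.seed)
    species = rng.choice(["human", "mouse", "ambiguous"], size=spec.n_reads,
                         p=[spec.fraction_human, spec.fraction_mouse,
                            spec.fraction_ambiguous])
    rows = []
    for i, sp in enumerate(species):
        if sp == "human":
            h, m, p = 1, 0, 1
        elif sp == "mouse":
            h, m, p = 0, 1, 0
        else:
            h, m, p = 1, 1, int(rng.random() < 0.5)
        rows.append({"read_id": f"r{i:06d}", "maps_human": h, "maps_mouse": m,
                     "primary_is_human": p, "truth": sp})
    return pd.DataFrame(rows, columns=["read_id", "maps_human", "maps_mouse",
                                       "primary_is_human", "truth"])


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantSimSpec:
    """How many records should be retained and how many should trip each
    cascade rule (each failing record violates exactly one rule)."""

    n_retained: int = 8
    n_fail_per_rule: Mapping[str, int] = field(
        default_factory=lambda: {rule: 2 for rule in CASCADE_RULES})
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.n_fail_per_rule) - set(CASCADE_RULES)
        if unknown:
            raise ValueError(f"unknown cascade rules: {sorted(unknown)}")
        if self.n_retained < 0 or any(v < 0 for v in
                                      self.n_fail_per_rule.values()):
            raise ValueError("negative record count")

    @property
    def n_variants(self) -> int:
        return self.n_retained + sum(self.n_fail_per_rule.values())


_RETAINED_TEMPLATES = (
    # (gene, role, in_cosmic) — all three retained archetypes
    ("BRAF", "oncogene", True),
    ("NRAS", "oncogene", True),
    ("TP53", "tumor_suppressor", True),
    ("NF1", "tumor_suppressor", False),   # novel TSG, clean context
)


def _base_record(rng: np.random.Generator, idx: int, gene: str, role: str,
                 in_cosmic: bool) -> dict:
    ref, alt = rng.choice(["A", "C", "G", "T"], size=2, replace=False)
    depth = int(rng.integers(20, 200))
    alt_reads = int(rng.integers(3, max(4, depth // 2)))
    return {
        "chrom": f"chr{int(rng.integers(1, 23))}",
        "pos": int(rng.integers(1, 10_000_000)),
        "ref": str(ref), "alt": str(alt),
        "depth": depth, "alt_reads": alt_reads,
        "vaf": alt_reads / depth,
        "avg_alt_quality": float(rng.uniform(20, 40)),
        "sample_id": f"S{idx:03d}", "source": "per_sample",
        "gene": gene, "region": "exonic", "consequence": "missense",
        "dbsnp_status": "absent", "in_cosmic": in_cosmic,
        "gene_role": role, "in_esp6500": False, "in_1000g": False,
        "homopolymer_adjacent": False, "end_of_read_only": False,
    }


def gen_variants(spec: VariantSimSpec) -> pd.DataFrame:
    """Annotated variant records with a ``truth_verdict`` column.

    Retained records cycle through the retained archetypes (COSMIC
    oncogene, COSMIC tumor suppressor, clean novel tumor suppressor);
    each failing record starts from a retained archetype and flips the
    single annotation that trips its target rule.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    idx = 0
    for i in range(spec.n_retained):
        gene, role, cosmic = _RETAINED_TEMPLATES[i % len(_RETAINED_TEMPLATES)]
        rec = _base_record(rng, idx, gene, role, cosmic)
        rec["truth_verdict"] = RETAINED
        rows.append(rec)
        idx += 1
    for rule in CASCADE_RULES:
        for _ in range(spec.n_fail_per_rule.get(rule, 0)):
            rec = _base_record(rng, idx, "BRAF", "oncogene", True)
            if rule == RULE_REGION:
                rec["region"] = str(rng.choice(["intronic", "UTR3",
                                                "intergenic"]))
            elif rule == RULE_SYNONYMOUS:
                rec["consequence"] = "synonymous"
            elif rule == RULE_DBSNP:
                rec["dbsnp_status"] = "nonflagged"
            elif rule == RULE_ONCOGENE:
                rec["in_cosmic"] = False
            elif rule == RULE_POPULATION:
                rec.update(gene="TP53", gene_role="tumor_suppressor",
                           in_cosmic=False)
                which = int(rng.integers(3))  # ESP, 1000G, or both
                rec["in_esp6500"] = which in (0, 2)
                rec["in_1000g"] = which in (1, 2)
            elif rule == RULE_ROLE:
                rec.update(gene="TTN", gene_role="other")
            elif rule == RULE_HOMOPOLYMER:
                rec.update(gene="NF1", gene_role="tumor_suppressor",
                           in_cosmic=False, homopolymer_adjacent=True)
            elif rule == RULE_READ_END:
                rec.update(gene="NF1", gene_role="tumor_suppressor",
                           in_cosmic=False, end_of_read_only=True)
            rec["truth_verdict"] = rule
            rows.append(rec)
            idx += 1
    columns = ["chrom", "pos", "ref", "alt", "depth", "alt_reads", "vaf",
               "avg_alt_quality", "sample_id", "source", *ANNOTATION_FIELDS,
               "truth_verdict"]
    return pd.DataFrame(rows, columns=columns)


def variants_from_sim(table: pd.DataFrame) -> list[AnnotatedVariant]:
    """Convert a gen_variants table to AnnotatedVariant records (the
    truth column stays behind in the table)."""
    out = []
    for _, row in table.iterrows():
        out.append(AnnotatedVariant(
            chrom=row["chrom"], pos=int(row["pos"]), ref=row["ref"],
            alt=row["alt"], depth=int(row["depth"]),
            alt_reads=int(row["alt_reads"]), vaf=float(row["vaf"]),
            avg_alt_quality=float(row["avg_alt_quality"]),
            sample_id=row["sample_id"], source=row["source"],
            gene=row["gene"], region=row["region"],
            consequence=row["consequence"], dbsnp_status=row["dbsnp_status"],
            in_cosmic=bool(row["in_cosmic"]), gene_role=row["gene_role"],
            in_esp6500=bool(row["in_esp6500"]), in_1000g=bool(row["in_1000g"]),
            homopolymer_adjacent=bool(row["homopolymer_adjacent"]),
            end_of_read_only=bool(row["end_of_read_only"])))
    return out


def gen_hotspot_cohort(n_samples: int = 31, n_braf: int = 20, n_nras: int = 11,
                       groups: Mapping[str, str] | None = None,
                       seed: int = 0) -> tuple[list[AnnotatedVariant], dict[str, str]]:
    """A retained hotspot variant set over a cohort: the first ``n_braf``
    samples carry a BRAF COSMIC variant and the last ``n_nras`` an NRAS
    one (mirroring the cohort's 20/31 and 11/31 prevalences). Returns the
    evaluated variants and a sample->group map."""
    from .variants import evaluate_variants

    rng = np.random.default_rng(seed)
    samples = [f"S{i:03d}" for i in range(n_samples)]
    if groups is None:
        cls = [PROGRESSION, SUPPRESSION, REGRESSION]
        groups = {s: cls[i % 3] for i, s in enumerate(samples)}
    recs = []
    for i, s in enumerate(samples):
        if i < n_braf:
            rec = _base_record(rng, i, "BRAF", "oncogene", True)
            rec.update(sample_id=s, chrom="chr7", pos=140453136,
                       ref="A", alt="T")  # BRAF V600E locus
            recs.append(rec)
        if i >= n_samples - n_nras:
            rec = _base_record(rng, i, "NRAS", "oncogene", True)
            rec.update(sample_id=s, chrom="chr1", pos=115256529,
                       ref="T", alt="C")  # NRAS Q61 locus
            recs.append(rec)
    table = pd.DataFrame(recs)
    variants = evaluate_variants(variants_from_sim(table))
    return variants, dict(groups)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def gen_counts(n_genes: int,
               n_samples: int,
               group_labels: Sequence[str],
               batch_labels: Sequence[str],
               abcb1_spec: Mapping | None = None,
               seed: int = 0,
               dispersion: float = 0.1,
               mean_log_mu: float = math.log(100.0),
               mean_log_sigma: float = 1.0,
               batch_log2_offset: float = 0.5,
               de_spec: Mapping | None = None,
               depth_factors: Sequence[float] | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial gene x sample counts with a batch covariate.

    Per-gene base means are log-normal; every batch after the first adds
    a log-additive offset of ``batch_log2_offset`` log2 units.
    ``abcb1_spec`` = {"gene", "high_samples", "high_mean", "low_mean"}
    plants a marker gene expressed above the high bin only in the chosen
    samples; ``de_spec`` = {"gene", "fold", "up_group"} plants one
    differentially expressed gene; ``depth_factors`` scale every gene's
    mean per sample (known sequencing-depth ground truth for size-factor
    recovery). Returns (counts, sample metadata).
    """
    if len(group_labels) != n_samples or len(batch_labels) != n_samples:
        raise ValueError("label lengths must equal n_samples")
    if depth_factors is not None and len(depth_factors) != n_samples:
        raise ValueError("depth_factors length must equal n_samples")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    samples = [f"S{i:03d}" for i in range(n_samples)]
    base = np.exp(rng.normal(mean_log_mu, mean_log_sigma, size=n_genes))
    mu = np.tile(base[:, None], (1, n_samples))

    batches = list(dict.fromkeys(batch_labels))
    for j, b in enumerate(batch_labels):
        mu[:, j] *= 2.0 ** (batch_log2_offset * batches.index(b))
    if depth_factors is not None:
        mu *= np.asarray(depth_factors, dtype=float)[None, :]

    counts = pd.DataFrame(0, index=genes, columns=samples, dtype=int)

    if de_spec is not None:
        gi = genes.index(de_spec["gene"]) if de_spec["gene"] in genes else None
        if gi is None:
            genes.append(de_spec["gene"])
            mu = np.vstack([mu, np.full(n_samples, 200.0)])
            gi = len(genes) - 1
            counts = counts.reindex(genes, fill_value=0)
        for j, g in enumerate(group_labels):
            if g == de_spec["up_group"]:
                mu[gi, j] *= de_spec["fold"]

    if abcb1_spec is not None:
        gene = abcb1_spec.get("gene", "ABCB1")
        high = set(abcb1_spec["high_samples"])
        if gene not in genes:
            genes.append(gene)
            mu = np.vstack([mu, np.zeros(n_samples)])
            counts = counts.reindex(genes, fill_value=0)
        gi = genes.index(gene)
        for j, s in enumerate(samples):
            mu[gi, j] = (abcb1_spec.get("high_mean", 5000.0) if s in high
                         else abcb1_spec.get("low_mean", 20.0))

    if dispersion > 0:
        size = 1.0 / dispersion
        p = size / (size + mu)
        draws = rng.negative_binomial(size, p)
    else:
        draws = rng.poisson(mu)
    counts.loc[:, :] = draws.astype(int)
    meta = pd.DataFrame({"sample_id": samples, "group": list(group_labels),
                         "batch": list(batch_labels)}).set_index("sample_id")
    return counts, meta
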