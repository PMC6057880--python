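"""Sensitive pileup variant calling and the annotation-driven retention
cascade used for hotspot screening in RNA-seq of PDX tumors.

The caller is a minimal threshold caller over pileup columns with the
sensitive settings used for low-coverage, allele-imbalanced RNA data
(min coverage 2, min supporting reads 2, min VAF 0.01, min average base
quality 15; all inclusive). Calls made per sample and on the pooled
cohort are merged by locus and sample. Annotated calls then run through
an ordered retention cascade:

1. discard variants outside exonic/splicing regions;
2. discard synonymous variants;
3. discard variants present in the non-flagged dbSNP set;
4. oncogenes: retain only known COSMIC variants;
5. tumor suppressors: retain COSMIC variants, and novel variants only
   when absent from both ESP6500 and 1000 Genomes;
6. genes with no oncogene/tumor-suppressor role are discarded;
7. novel (non-COSMIC) survivors adjacent to homopolymer runs or supported
   only at read ends are discarded.

Each verdict names the first failing rule. Calls with very few supporting
reads and calls rescued manually from visual inspection are flagged low
confidence; the final retained set is laid out as an oncoprint
(gene x sample matrix grouped by response class).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGT")

RETAINED = "retained"
RULE_REGION = "discarded:region"
RULE_SYNONYMOUS = "discarded:synonymous"
RULE_DBSNP = "discarded:dbsnp"
RULE_ONCOGENE = "discarded:oncogene_non_cosmic"
RULE_POPULATION = "discarded:population_db"
RULE_ROLE = "discarded:gene_role"
RULE_HOMOPOLYMER = "discarded:homopolymer"
RULE_READ_END = "discarded:read_end"
CASCADE_RULES = (RULE_REGION, RULE_SYNONYMOUS, RULE_DBSNP, RULE_ONCOGENE,
                 RULE_POPULATION, RULE_ROLE, RULE_HOMOPOLYMER, RULE_READ_END)

#: Regions retained by rule 1.
CODING_REGIONS = frozenset({"exonic", "splicing"})

#: Gene roles for the melanoma hotspot panel; a user role table may
#: override or extend this.
DEFAULT_GENE_ROLES: dict[str, str] = {
    "BRAF": "oncogene",
    "NRAS": "oncogene",
    "KIT": "oncogene",
    "GNAQ": "oncogene",
    "GNA11": "oncogene",
    "NF1": "tumor_suppressor",
    "TP53": "tumor_suppressor",
    "CDKN2A": "tumor_suppressor",
    "PTEN": "tumor_suppressor",
    "DDX3X": "tumor_suppressor",
    "ARID2": "tumor_suppressor",
}


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PileupColumn:
    """One pileup column: reference context plus per-read (base, quality)
    observations. Positions are 1-based."""

    chrom: str
    pos: int
    ref_base: str
    observations: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("positions are 1-based")
        if self.ref_base not in VALID_BASES:
            raise ValueError(f"invalid reference base {self.ref_base!r}")
        for base, qual in self.observations:
            if base not in VALID_BASES:
                raise ValueError(f"invalid observed base {base!r}")
            if qual < 0:
                raise ValueError("negative base quality")


@dataclass(frozen=True)
class CallerThresholds:
    """Inclusive thresholds of the sensitive caller.

    ``min_base_quality`` is a separate per-observation floor: observations
    below it are excluded from support counting but still count toward
    depth. It defaults to 0 (all observations support).
    """

    min_coverage: int = 2
    min_reads2: int = 2
    min_var_freq: float = 0.01
    min_avg_qual: float = 15.0
    min_base_quality: float = 0.0


@dataclass(frozen=True)
class VariantCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_reads: int
    vaf: float
    avg_alt_quality: float
    sample_id: str
    source: str = "per_sample"  # per_sample | pooled | manual

    def __post_init__(self) -> None:
        if self.alt_reads > self.depth:
            raise ValueError("alt_reads exceeds depth")

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)


def call_pileup(columns: Iterable[PileupColumn],
                thresholds: CallerThresholds = CallerThresholds(),
                sample_id: str = "sample",
                source: str = "per_sample") -> list[VariantCall]:
    """Threshold caller: emit a call for every non-reference base that
    clears all four inclusive thresholds at its column.

    Depth counts every observation; support counts observations at or
    above ``min_base_quality``; VAF is support over depth; the average
    quality is taken over the supporting observations.
    """
    calls: list[VariantCall] = []
    for col in columns:
        depth = len(col.observations)
        if depth < thresholds.min_coverage:
            continue
        for alt in sorted(VALID_BASES - {col.ref_base}):
            quals = [q for b, q in col.observations
                     if b == alt and q >= thresholds.min_base_quality]
            support = len(quals)
            if support == 0 or support < thresholds.min_reads2:
                continue
            vaf = support / depth
            if vaf < thresholds.min_var_freq:
                continue
            avg_q = sum(quals) / support
            if avg_q < thresholds.min_avg_qual:
                continue
            calls.append(VariantCall(col.chrom, col.pos, col.ref_base, alt,
                                     depth, support, vaf, avg_q,
                                     sample_id, source))
    return calls


def merge_callsets(per_sample_sets: Iterable[Sequence[VariantCall]],
                   pooled_set: Sequence[VariantCall] = ()) -> list[VariantCall]:
    """Merge per-sample call sets with the pooled-cohort call set.

    The union is keyed on (sample, chrom, pos, ref, alt); when the same
    key was called twice the record with more supporting reads wins (ties
    keep the earlier record), preserving its source. A conflicting
    reference base at one locus is an input error.
    """
    merged: dict[tuple, VariantCall] = {}
    ref_at: dict[tuple[str, int], str] = {}
    for callset in list(per_sample_sets) + [pooled_set]:
        for call in callset:
            locus = (call.chrom, call.pos)
            if locus in ref_at and ref_at[locus] != call.ref:
                raise ValueError(
                    f"conflicting reference base at {call.chrom}:{call.pos}: "
                    f"{ref_at[locus]} vs {call.ref}")
            ref_at[locus] = call.ref
            prev = merged.get(call.key)
            if prev is None or call.alt_reads > prev.alt_reads:
                merged[call.key] = call
    return sorted(merged.values(),
                  key=lambda c: (c.sample_id, c.chrom, c.pos, c.alt))


# ---------------------------------------------------------------------------
# the retention cascade
# ---------------------------------------------------------------------------

ANNOTATION_FIELDS = ("gene", "region", "consequence", "dbsnp_status",
                     "in_cosmic", "gene_role", "in_esp6500", "in_1000g",
                     "homopolymer_adjacent", "end_of_read_only")


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant call plus the annotations the cascade consumes and, once
    evaluated, its confidence flag and verdict."""

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_reads: int
    vaf: float
    avg_alt_quality: float
    sample_id: str
    source: str
    gene: str
    region: str
    consequence: str
    dbsnp_status: str        # absent | flagged | nonflagged
    in_cosmic: bool
    gene_role: str           # oncogene | tumor_suppressor | other
    in_esp6500: bool
    in_1000g: bool
    homopolymer_adjacent: bool
    end_of_read_only: bool
    confidence: str | None = None
    verdict: str | None = None


def filter_cascade(v: AnnotatedVariant | Mapping) -> str:
    """Run one annotated variant through the ordered retention cascade and
    return ``"retained"`` or ``"discarded:<rule>"`` naming the first
    failing rule. A pure per-record function.
    """
    get = (lambda k: getattr(v, k)) if isinstance(v, AnnotatedVariant) \
        else (lambda k: v[k])
    for name in ANNOTATION_FIELDS:
        val = get(name)
        if val is None or (isinstance(val, float) and math.isnan(val)):
            raise ValueError(f"missing annotation {name!r}")

    if get("region") not in CODING_REGIONS:
        return RULE_REGION
    if get("consequence") == "synonymous":
        return RULE_SYNONYMOUS
    if get("dbsnp_status") == "nonflagged":
        return RULE_DBSNP

    role = get("gene_role")
    in_cosmic = bool(get("in_cosmic"))
    if role == "oncogene":
        if not in_cosmic:
            return RULE_ONCOGENE
    elif role == "tumor_suppressor":
        if not in_cosmic and (bool(get("in_esp6500")) or bool(get("in_1000g"))):
            return RULE_POPULATION
    else:
        return RULE_ROLE

    if not in_cosmic:  # novel call: demand a clean read context
        if bool(get("homopolymer_adjacent")):
            return RULE_HOMOPOLYMER
        if bool(get("end_of_read_only")):
            return RULE_READ_END
    return RETAINED


def flag_confidence(v: AnnotatedVariant | VariantCall,
                    low_support_threshold: int = 2) -> str:
    """``low`` when a call rests on very few supporting reads (default
    <= 2) or was rescued manually, else ``high``."""
    if v.alt_reads <= low_support_threshold or v.source == "manual":
        return "low"
    return "high"


def evaluate_variants(variants: Iterable[AnnotatedVariant],
                      low_support_threshold: int = 2) -> list[AnnotatedVariant]:
    """Attach cascade verdict and confidence flag to every record."""
    return [replace(v, verdict=filter_cascade(v),
                    confidence=flag_confidence(v, low_support_threshold))
            for v in variants]


def apply_whitelist(variants: Sequence[AnnotatedVariant],
                    whitelist: Iterable[tuple[str, str, int, str, str]]) -> list[AnnotatedVariant]:
    """Manual rescue: records whose (sample, chrom, pos, ref, alt) appear
    on the whitelist bypass the cascade — they are retained, re-sourced as
    ``manual`` and therefore flagged low confidence."""
    wl = set(whitelist)
    out = []
    for v in variants:
        if (v.sample_id, v.chrom, v.pos, v.ref, v.alt) in wl:
            v = replace(v, source="manual", verdict=RETAINED, confidence="low")
        out.append(v)
    return out


def homopolymer_adjacent(context_sequence: str, variant_offset: int,
                         run_min: int = 5, adjacency: int = 1) -> bool:
    """Whether a variant sits in or next to a homopolymer run.

    True iff a single-base run of length >= ``run_min`` starts or ends
    within ``adjacency`` bases of ``variant_offset`` (0-based within the
    context window); a variant inside such a run also qualifies.
    """
    seq = context_sequence.upper()
    if len(seq) < run_min:
        raise ValueError("context window shorter than the minimum run length")
    if not (0 <= variant_offset < len(seq)):
        raise ValueError("variant offset outside the context window")
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            run_len = i - start
            if run_len >= run_min:
                if start - adjacency <= variant_offset <= i - 1 + adjacency:
                    return True
            start = i
    return False


def end_of_read_only(read_offsets: Sequence[tuple[int, int]],
                     end_margin: int = 5) -> bool:
    """Whether every supporting read places the variant near a read end.

    ``read_offsets`` holds (offset_from_start, offset_from_end) pairs, one
    per supporting read; True iff each pair has min(offsets) < end_margin.
    """
    if len(read_offsets) == 0:
        raise ValueError("no supporting reads")
    return all(min(a, b) < end_margin for a, b in read_offsets)


# ---------------------------------------------------------------------------
# oncoprint
# ---------------------------------------------------------------------------

CELL_NONE = "none"
CELL_HIGH = "mutated_high_conf"
CELL_LOW = "mutated_low_conf"

_GROUP_ORDER = {"progression": 0, "suppression": 1, "regression": 2}


def oncoprint(variants: Sequence[AnnotatedVariant],
              samples: Sequence[str],
              genes: Sequence[str],
              groups: Mapping[str, str]) -> pd.DataFrame:
    """Gene x sample mutation matrix from the retained variant set.

    Columns are ordered progression, suppression, regression (stable
    within a group); each cell is ``none``, ``mutated_high_conf`` or
    ``mutated_low_conf``, multiple variants collapsing to the highest
    confidence. Column group labels ride along in ``DataFrame.attrs``.
    """
    for s in samples:
        if s not in groups:
            raise ValueError(f"sample {s!r} has no response-group label")
    ordered = sorted(samples, key=lambda s: (_GROUP_ORDER.get(groups[s], 99),
                                             samples.index(s)))
    mat = pd.DataFrame(CELL_NONE, index=list(genes), columns=ordered)
    for v in variants:
        if v.verdict != RETAINED:
            raise ValueError("oncoprint expects retained variants only")
        if v.gene not in mat.index or v.sample_id not in mat.columns:
            continue
        state = CELL_HIGH if v.confidence == "high" else CELL_LOW
        if mat.at[v.gene, v.sample_id] != CELL_HIGH:
            mat.at[v.gene, v.sample_id] = state
    mat.attrs["groups"] = {s: groups[s] for s in ordered}
    return mat


def mutation_prevalence(matrix: pd.DataFrame) -> dict[str, int]:
    """Per-gene mutated-sample percentage (any confidence), rounded half
    away from zero — e.g. 20 of 31 BRAF-mutant samples reports 65."""
    from .growth import round_half_away

    n = matrix.shape[1]
    if n == 0:
        raise ValueError("empty oncoprint")
    return {gene: round_half_away(100.0 * (matrix.loc[gene] != CELL_NONE).sum() / n)
            for gene in matrix.index}


def plot_oncoprint(matrix: pd.DataFrame, path: str | None = None):
    """Simple tile plot of an oncoprint matrix (transparent tiles mark
    low-confidence calls)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    group_colors = {"progression": "#3b6fb5", "suppression": "#e8c547",
                    "regression": "#c0392b"}
    groups = matrix.attrs.get("groups", {})
    fig, ax = plt.subplots(figsize=(0.3 * matrix.shape[1] + 2,
                                    0.35 * matrix.shape[0] + 1))
    for gi, gene in enumerate(matrix.index):
        for si, sample in enumerate(matrix.columns):
            cell = matrix.at[gene, sample]
            if cell == CELL_NONE:
                face, alpha = "#dddddd", 1.0
            else:
                face = group_colors.get(groups.get(sample), "#444444")
                alpha = 1.0 if cell == CELL_HIGH else 0.35
            ax.add_patch(Rectangle((si, matrix.shape[0] - 1 - gi), 0.9, 0.9,
                                   facecolor=face, alpha=alpha))
    ax.set_xlim(0, matrix.shape[1])
    ax.set_ylim(0, matrix.shape[0])
    ax.set_yticks([matrix.shape[0] - 1 - i + 0.45 for i in range(matrix.shape[0])])
    ax.set_yticklabels(matrix.index)
    ax.set_xticks([])
    if path:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

VARIANT_TSV_COLUMNS = ("chrom", "pos", "ref", "alt", "depth", "alt_reads",
                       "vaf", "avg_alt_quality", "sample_id", "source",
                       *ANNOTATION_FIELDS, "confidence", "verdict")

_BOOL_FIELDS = ("in_cosmic", "in_esp6500", "in_1000g",
                "homopolymer_adjacent", "end_of_read_only")


def variants_to_frame(variants: Iterable[AnnotatedVariant]) -> pd.DataFrame:
    rows = []
    for v in variants:
        row = {c: getattr(v, c) for c in VARIANT_TSV_COLUMNS}
        for b in _BOOL_FIELDS:
            row[b] = int(row[b])
        rows.append(row)
    return pd.DataFrame(rows, columns=list(VARIANT_TSV_COLUMNS))


def frame_to_variants(df: pd.DataFrame) -> list[AnnotatedVariant]:
    out = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in VARIANT_TSV_COLUMNS if c in row}
        for b in _BOOL_FIELDS:
            kwargs[b] = bool(int(kwargs[b]))
        kwargs["pos"] = int(kwargs["pos"])
        kwargs["depth"] = int(kwargs["depth"])
        kwargs["alt_reads"] = int(kwargs["alt_reads"])
        for opt in ("confidence", "verdict"):
            if opt in kwargs and (kwargs[opt] is None or
                                  (isinstance(kwargs[opt], float) and
                                   math.isnan(kwargs[opt]))):
                kwargs[opt] = None
        out.append(AnnotatedVariant(**kwargs))
    return out


_VCF_INFO = [
    ("GENE", "String", "Gene symbol"),
    ("REGION", "String", "Genomic region class"),
    ("CSQ", "String", "Coding consequence"),
    ("DBSNP", "String", "dbSNP status: absent/flagged/nonflagged"),
    ("COSMIC", "Integer", "Known COSMIC variant (0/1)"),
    ("ROLE", "String", "Gene role: oncogene/tumor_suppressor/other"),
    ("ESP", "Integer", "Present in ESP6500 (0/1)"),
    ("KG", "Integer", "Present in 1000 Genomes (0/1)"),
    ("HP_ADJ", "Integer", "Adjacent to homopolymer run (0/1)"),
    ("EOR", "Integer", "Supported only at read ends (0/1)"),
    ("DP", "Integer", "Total depth"),
    ("SUP", "Integer", "Supporting (alt) reads"),
    ("VAF", "Float", "Variant allele fraction"),
    ("AQ", "Float", "Mean quality of supporting reads"),
    ("SAMPLE", "String", "Sample id"),
    ("SRC", "String", "Call source: per_sample/pooled/manual"),
    ("CONF", "String", "Confidence: high/low"),
    ("VERDICT", "String", "Cascade verdict"),
]


def write_vcf(variants: Sequence[AnnotatedVariant], path: str) -> None:
    """Write annotated variants as a VCF with the annotations in INFO."""
    import pysam

    header = pysam.VariantHeader()
    for name, typ, desc in _VCF_INFO:
        header.info.add(name, 1, typ, desc)
    for chrom in sorted({v.chrom for v in variants}):
        header.contigs.add(chrom)
    with pysam.VariantFile(path, "w", header=header) as out:
        for v in sorted(variants, key=lambda x: (x.chrom, x.pos, x.alt,
                                                 x.sample_id)):
            rec = out.new_record(contig=v.chrom, start=v.pos - 1,
                                 stop=v.pos, alleles=(v.ref, v.alt))
            rec.info["GENE"] = v.gene
            rec.info["REGION"] = v.region
            rec.info["CSQ"] = v.consequence
            rec.info["DBSNP"] = v.dbsnp_status
            rec.info["COSMIC"] = int(v.in_cosmic)
            rec.info["ROLE"] = v.gene_role
            rec.info["ESP"] = int(v.in_esp6500)
            rec.info["KG"] = int(v.in_1000g)
            rec.info["HP_ADJ"] = int(v.homopolymer_adjacent)
            rec.info["EOR"] = int(v.end_of_read_only)
            rec.info["DP"] = v.depth
            rec.info["SUP"] = v.alt_reads
            rec.info["VAF"] = v.vaf
            rec.info["AQ"] = v.avg_alt_quality
            rec.info["SAMPLE"] = v.sample_id
            rec.info["SRC"] = v.source
            if v.confidence is not None:
                rec.info["CONF"] = v.confidence
            if v.verdict is not None:
                rec.info["VERDICT"] = v.verdict
            out.write(rec)


def read_vcf(path: str) -> list[AnnotatedVariant]:
    """Read annotated variants written by :func:`write_vcf`."""
    import pysam

    out = []
    with pysam.VariantFile(path) as fh:
        for rec in fh:
            info = rec.info
            out.append(AnnotatedVariant(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref,
                alt=rec.alts[0],
                depth=int(info["DP"]), alt_reads=int(info["SUP"]),
                vaf=float(info["VAF"]), avg_alt_quality=float(info["AQ"]),
                sample_id=str(info["SAMPLE"]), source=str(info["SRC"]),
                gene=str(info["GENE"]), region=str(info["REGION"]),
                consequence=str(info["CSQ"]),
                dbsnp_status=str(info["DBSNP"]),
                in_cosmic=bool(info["COSMIC"]),
                gene_role=str(info["ROLE"]),
                in_esp6500=bool(info["ESP"]), in_1000g=bool(info["KG"]),
                homopolymer_adjacent=bool(info["HP_ADJ"]),
                end_of_read_only=bool(info["EOR"]),
                confidence=str(info["CONF"]) if "CONF" in info else None,
                verdict=str(info["VERDICT"]) if "VERDICT" in info else None))
    return out


def read_pileup_tsv(path: str) -> list[PileupColumn]:
    """Read a samtools-mpileup-like TSV: chrom, pos, ref, bases, quals
    where ``bases`` is a string of observed bases and ``quals`` a
    comma-separated list of numeric qualities."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    cols = []
    for _, row in df.iterrows():
        bases = str(row["bases"]) if not pd.isna(row["bases"]) else ""
        quals = ([float(q) for q in str(row["quals"]).split(",") if q != ""]
                 if not pd.isna(row["quals"]) else [])
        if len(bases) != len(quals):
            raise ValueError(f"bases/quals length mismatch at "
                             f"{row['chrom']}:{row['pos']}")
        cols.append(PileupColumn(str(row["chrom"]), int(row["pos"]),
                                 str(row["ref"]),
                                 tuple(zip(bases, quals))))
    return cols
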