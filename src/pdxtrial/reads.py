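"""Graft-versus-host read disambiguation for xenograft sequencing.

PDX tumor samples contain mouse stroma, so reads are aligned against a
combined human+mouse reference and assigned to a species before variant
calling. The decision rule per read:

* maps to human only            -> keep (``keep_human``)
* maps to mouse only            -> drop (``drop_mouse``)
* maps to both organisms        -> keep only if its primary alignment is
                                   against the human reference, else drop
                                   (``drop_ambiguous``)

This minimizes false-positive variant calls caused by mouse reads landing
on homologous human loci.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

KEEP_HUMAN = "keep_human"
DROP_MOUSE = "drop_mouse"
DROP_AMBIGUOUS = "drop_ambiguous"
VERDICTS = (KEEP_HUMAN, DROP_MOUSE, DROP_AMBIGUOUS)

READ_COLUMNS = ("read_id", "maps_human", "maps_mouse", "primary_is_human")


def assign_read(maps_human: bool, maps_mouse: bool,
                primary_is_human: bool) -> str:
    """Species verdict for one read from its three mapping flags.

    ``primary_is_human`` is consulted only for reads mapping to both
    organisms. Reads mapping to neither are out of band and rejected.
    """
    if not (maps_human or maps_mouse):
        raise ValueError("read maps to neither organism (unmapped reads are "
                         "out of band)")
    if maps_human and not maps_mouse:
        return KEEP_HUMAN
    if maps_mouse and not maps_human:
        return DROP_MOUSE
    return KEEP_HUMAN if primary_is_human else DROP_AMBIGUOUS


def filter_read_table(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the species rule to a per-read flag table.

    Returns ``(kept, counts)`` where ``kept`` holds the rows with verdict
    ``keep_human`` (plus a ``verdict`` column) and ``counts`` has one
    entry per verdict; the verdict counts always sum to the input size.
    Duplicate read ids with conflicting flags are rejected with their row
    numbers.
    """
    missing = set(READ_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"read table missing columns: {sorted(missing)}")
    if len(table) == 0:
        empty = table.copy()
        empty["verdict"] = pd.Series(dtype=str)
        return empty, {v: 0 for v in VERDICTS}

    dup = table[table.duplicated("read_id", keep=False)]
    if len(dup):
        for _, grp in dup.groupby("read_id"):
            flags = grp[["maps_human", "maps_mouse", "primary_is_human"]]
            if flags.drop_duplicates().shape[0] > 1:
                rows = list(grp.index)
                raise ValueError(
                    f"read {grp['read_id'].iloc[0]!r} has conflicting flags "
                    f"in rows {rows}")

    out = table.copy()
    out["verdict"] = [
        assign_read(bool(h), bool(m), bool(p))
        for h, m, p in zip(out["maps_human"], out["maps_mouse"],
                           out["primary_is_human"])
    ]
    counts = {v: int((out["verdict"] == v).sum()) for v in VERDICTS}
    kept = out[out["verdict"] == KEEP_HUMAN].copy()
    return kept, counts


def sam_to_read_table(path: str,
                      human_prefix: str = "hg19_",
                      mouse_prefix: str = "mm10_") -> pd.DataFrame:
    """Extract per-read species flags from a SAM/BAM against a combined
    reference whose contig names carry species prefixes.

    Any alignment to a human-prefixed contig sets ``maps_human`` (same for
    mouse); multi-mapping within one species collapses to the single
    flag. ``primary_is_human`` is True when the read's primary alignment
    (not secondary, not supplementary) is on a human contig.
    """
    import pysam

    flags: dict[str, dict[str, bool]] = {}
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.reference_name is None:
                continue
            ref = aln.reference_name
            entry = flags.setdefault(aln.query_name, {
                "maps_human": False, "maps_mouse": False,
                "primary_is_human": False})
            if ref.startswith(human_prefix):
                entry["maps_human"] = True
                if not aln.is_secondary and not aln.is_supplementary:
                    entry["primary_is_human"] = True
            elif ref.startswith(mouse_prefix):
                entry["maps_mouse"] = True
            else:
                raise ValueError(f"contig {ref!r} matches neither species "
                                 "prefix")
    return pd.DataFrame({
        "read_id": list(flags),
        "maps_human": [int(v["maps_human"]) for v in flags.values()],
        "maps_mouse": [int(v["maps_mouse"]) for v in flags.values()],
        "primary_is_human": [int(v["primary_is_human"]) for v in flags.values()],
    })
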