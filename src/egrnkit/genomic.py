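"""Interval arithmetic, gene-activity scoring, pseudobulk and overlap statistics.

Coordinates are BED-convention throughout: 0-based, half-open [start, end).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "GenomicIntervalSet",
    "merge_intervals",
    "gene_activity_scores",
    "pseudobulk_log2cpm",
    "overlap_percentage",
]


class GenomicIntervalSet:
    """A validated table of genomic intervals (chrom, start, end, strand, id).

    Thin wrapper over a pandas DataFrame; iteration per chromosome is sorted
    by (start, end).
    """

    REQUIRED = ("chrom", "start", "end")

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"interval table missing column {col!r}")
        if "id" not in df.columns:
            df["id"] = [f"iv{i}" for i in range(len(df))]
        if "strand" not in df.columns:
            df["strand"] = "."
        bad = df.index[~(df.start < df.end)]
        if len(bad):
            rec = df.loc[bad[0]]
            raise ValueError(
                f"malformed interval {rec['id']!r}: start {rec['start']} >= end {rec['end']}"
            )
        bad_strand = set(df.strand.unique()) - {"+", "-", "."}
        if bad_strand:
            raise ValueError(f"unknown strand symbol(s): {sorted(bad_strand)}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def sorted(self) -> pd.DataFrame:
        return self.df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(
            drop=True
        )

    def by_chrom(self):
        for chrom, sub in self.sorted().groupby("chrom", sort=True):
            yield chrom, sub


def merge_intervals(intervals: GenomicIntervalSet) -> GenomicIntervalSet:
    """Minimal non-overlapping cover of the input, merging touching intervals.

    Follows the GenomicRanges ``reduce`` convention: intervals with
    ``end == start`` of the next are merged into one.
    """
    rows = []
    k = 0
    for chrom, sub in intervals.by_chrom():
        starts = sub.start.to_numpy()
        ends = sub.end.to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:  # overlap or touch
                cur_e = max(cur_e, int(e))
            else:
                rows.append((chrom, cur_s, cur_e, ".", f"merged{k}"))
                k += 1
                cur_s, cur_e = int(s), int(e)
        rows.append((chrom, cur_s, cur_e, ".", f"merged{k}"))
        k += 1
    return GenomicIntervalSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "id"])
    )


def _tss_and_window(genes: pd.DataFrame, upstream: int):
    """Strand-aware scoring window: gene body plus ``upstream`` bp 5' of it."""
    if not set(genes.strand.unique()) <= {"+", "-"}:
        bad = sorted(set(genes.strand.unique()) - {"+", "-"})
        raise ValueError(f"unknown strand symbol(s) for gene-activity scoring: {bad}")
    lo = np.where(genes.strand == "+", genes.start - upstream, genes.start)
    hi = np.where(genes.strand == "+", genes.end, genes.end + upstream)
    return np.maximum(lo, 0), hi


def gene_activity_scores(fragments: pd.DataFrame, genes: GenomicIntervalSet,
                         upstream: int = 2000, per_fragment: bool = False) -> pd.DataFrame:
    """Count Tn5 insertion sites per (gene, barcode) in gene body + upstream.

    Each fragment contributes its two cut sites, at positions ``start`` and
    ``end - 1``, counted independently (a fragment can contribute 0, 1 or 2).
    With ``per_fragment=True`` a fragment contributes at most 1, counted if
    either cut site falls in the window.

    Returns a gene x barcode integer DataFrame.
    """
    for col in ("chrom", "start", "end", "barcode"):
        if col not in fragments.columns:
            raise ValueError(f"fragment table missing column {col!r}")
    if (fragments.start >= fragments.end).any():
        bad = fragments.index[(fragments.start >= fragments.end)][0]
        raise ValueError(f"malformed fragment at row {bad}: start >= end")
    gdf = genes.df
    lo, hi = _tss_and_window(gdf, upstream)
    barcodes = pd.Index(sorted(fragments.barcode.unique()), name="barcode")
    out = pd.DataFrame(
        0, index=pd.Index(gdf["id"], name="gene_id"), columns=barcodes, dtype=int
    )
    bc_codes = barcodes.get_indexer(fragments.barcode)
    cut1 = fragments.start.to_numpy()
    cut2 = fragments.end.to_numpy() - 1
    fchrom = fragments.chrom.to_numpy()
    for gi, (chrom, a, b) in enumerate(zip(gdf.chrom, lo, hi)):
        on = fchrom == chrom
        in1 = on & (cut1 >= a) & (cut1 < b)
        in2 = on & (cut2 >= a) & (cut2 < b)
        if per_fragment:
            hits = (in1 | in2).astype(int)
        else:
            hits = in1.astype(int) + in2.astype(int)
        if hits.any():
            out.iloc[gi] += np.bincount(bc_codes, weights=hits, minlength=len(barcodes)).astype(
                int
            )
    return out


def pseudobulk_log2cpm(counts: pd.DataFrame, groups: pd.Series | dict,
                       pseudocount: float = 1.0) -> pd.DataFrame:
    """Aggregate nuclei into groups and return log2(CPM + pseudocount).

    ``counts`` is feature x nucleus; ``groups`` maps nucleus -> group label
    and must cover every column. Per group, counts are summed over nuclei,
    scaled to counts-per-million, then log2-transformed. A second level of
    averaging (e.g., donors within a stage) is a plain mean of these log
    values and is left to the caller.
    """
    groups = pd.Series(groups)
    missing = counts.columns.difference(groups.index)
    if len(missing):
        raise ValueError(f"nuclei without a group assignment: {list(missing[:5])}")
    out = {}
    for g, cols in counts.columns.to_series().groupby(groups.loc[counts.columns].to_numpy()):
        total = counts[cols].to_numpy().sum(axis=1)
        depth = total.sum()
        if depth == 0:
            raise ValueError(f"group {g!r} has zero total counts")
        out[g] = np.log2(total / depth * 1e6 + pseudocount)
    return pd.DataFrame(out, index=counts.index)


def overlap_percentage(query: GenomicIntervalSet, reference: GenomicIntervalSet,
                       min_overlap: int = 1):
    """Fraction of query intervals overlapping the reference by >= min_overlap bp.

    Returns ``(fraction, flags)`` where ``flags`` is a boolean Series indexed
    by query interval id. Used to summarize validation of called cis-elements
    against an external peak set (e.g. CUT&Tag peaks).
    """
    if len(query) == 0:
        raise ValueError("overlap fraction undefined for an empty query set")
    merged = merge_intervals(reference).df
    flags = np.zeros(len(query.df), dtype=bool)
    qdf = query.df
    for chrom, ref in merged.groupby("chrom"):
        rs = ref.start.to_numpy()
        re_ = ref.end.to_numpy()
        mask = (qdf.chrom == chrom).to_numpy()
        if not mask.any():
            continue
        qs = qdf.start.to_numpy()[mask]
        qe = qdf.end.to_numpy()[mask]
        # merged intervals are disjoint and sorted: candidates are those with
        # end > query start and start < query end
        lo = np.searchsorted(re_, qs, side="right")
        hi = np.searchsorted(rs, qe, side="left")
        hit = np.zeros(len(qs), dtype=bool)
        for i, (a, b) in enumerate(zip(lo, hi)):
            if b > a:
                ov = np.minimum(qe[i], re_[a:b]) - np.maximum(qs[i], rs[a:b])
                hit[i] = ov.max() >= min_overlap
        flags[np.where(mask)[0]] = hit
    frac = float(flags.mean())
    return frac, pd.Series(flags, index=pd.Index(qdf["id"], name="id"))
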