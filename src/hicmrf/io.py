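"""Reading contact matrices and covariate sources; writing calls.

Conventions: BED and bedGraph coordinates are 0-based half-open, GFF is
1-based inclusive; internally everything is 0-based half-open.  Strand is
ignored (contact-matrix bins are unstranded).  Genomic distance between a
pair of bins is measured between bin midpoints in bp; on the diagonal
(i = j) it is replaced by pseudocount * bin_size so its log stays finite.
Covariates averaged over the two bins are floored at small per-covariate
pseudocounts before the log transform (TE counts at 0.5 by additive
smoothing; GC and accessibility at 0.01, far below any real value, so the
floor only rescues genuinely empty bins).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .lattice import PairLattice
from .observations import Observations
from .selection import InteractionCall

__all__ = [
    "GenomicBin",
    "FormatError",
    "make_bins",
    "read_contact_matrix",
    "compute_gc_track",
    "compute_interval_track",
    "compute_signal_track",
    "read_bed_intervals",
    "assemble_observations",
    "write_calls_bedpe",
    "read_calls_bedpe",
    "DEFAULT_PSEUDOCOUNTS",
]

DEFAULT_PSEUDOCOUNTS = {"D": 0.5, "GC": 0.01, "TE": 0.5, "ACC": 0.01}


class FormatError(ValueError):
    """Malformed input file (message carries the line number)."""


@dataclass(frozen=True)
class GenomicBin:
    chrom: str
    start: int
    end: int
    index: int


def make_bins(chrom: str, chrom_length: int, bin_size: int, n_bins: int | None = None) -> list[GenomicBin]:
    """Consecutive fixed-size bins along a chromosome (last bin may be short)."""
    if bin_size < 1 or chrom_length < 1:
        raise ValueError("bin_size and chrom_length must be positive")
    bins = []
    idx = 0
    for start in range(0, chrom_length, bin_size):
        bins.append(GenomicBin(chrom, start, min(start + bin_size, chrom_length), idx))
        idx += 1
        if n_bins is not None and idx >= n_bins:
            break
    return bins


# ---------------------------------------------------------------------------
# contact matrix
# ---------------------------------------------------------------------------

def read_contact_matrix(
    path: str | Path,
    n_bins: int,
    bin_size: int | None = None,
    chrom: str | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read sparse triplet text and return the dense upper-triangle region.

    Two tab/space-delimited dialects are auto-detected from the column
    count: ``(i, j, count)`` with integer bin indices, or
    ``(chrom, start1, chrom, start2, count)`` with bp coordinates (needs
    ``bin_size``; ``chrom`` filters rows when given).  Entries are
    canonicalized to i <= j; a (j, i) duplicate must agree with its (i, j)
    mirror.  Pairs absent from the file are filled with zero, so the result
    always enumerates all n_bins * (n_bins + 1) / 2 pairs (diagonal
    included) as arrays (i, j, y) in row-major upper-triangle order.
    """
    counts: dict[tuple[int, int], int] = {}
    n_cols = None
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if n_cols is None:
                n_cols = len(fields)
                if n_cols not in (3, 5):
                    raise FormatError(f"line {ln}: expected 3 or 5 columns, got {n_cols}")
                if n_cols == 5 and bin_size is None:
                    raise FormatError("coordinate dialect requires bin_size")
            if len(fields) != n_cols:
                raise FormatError(f"line {ln}: mixed dialects ({len(fields)} vs {n_cols} columns)")
            try:
                if n_cols == 3:
                    i, j = int(fields[0]), int(fields[1])
                    y_raw = fields[2]
                else:
                    if chrom is not None and (fields[0] != chrom or fields[2] != chrom):
                        continue
                    i, j = int(fields[1]) // bin_size, int(fields[3]) // bin_size
                    y_raw = fields[4]
                y = int(y_raw)
                if float(y_raw) != y:
                    raise ValueError
            except ValueError:
                raise FormatError(f"line {ln}: non-integer bin index or count") from None
            if y < 0:
                raise FormatError(f"line {ln}: negative count {y}")
            if i < 0 or j < 0 or i >= n_bins or j >= n_bins:
                raise FormatError(f"line {ln}: bin index outside requested region")
            if i > j:
                i, j = j, i
            if (i, j) in counts and counts[(i, j)] != y:
                raise FormatError(
                    f"line {ln}: symmetric duplicate ({i},{j}) disagrees "
                    f"({counts[(i, j)]} vs {y})"
                )
            counts[(i, j)] = y
    ii, jj = np.triu_indices(n_bins)
    yy = np.array([counts.get((int(a), int(b)), 0) for a, b in zip(ii, jj)], dtype=np.int64)
    return ii.astype(np.int64), jj.astype(np.int64), yy


# ---------------------------------------------------------------------------
# covariate tracks
# ---------------------------------------------------------------------------

def compute_gc_track(
    fasta: str | Path, bins: Sequence[GenomicBin], missing_value: float = 0.5
) -> np.ndarray:
    """Per-bin GC fraction (#G + #C) / #ACGT; ambiguous bases are excluded
    from the denominator and an all-ambiguous bin gets ``missing_value``."""
    from pyfaidx import Fasta

    fa = Fasta(str(fasta), as_raw=True, sequence_always_upper=True)
    out = np.empty(len(bins))
    for b, gb in enumerate(bins):
        if gb.chrom not in fa:
            raise KeyError(f"chromosome {gb.chrom!r} not in FASTA")
        seq = str(fa[gb.chrom][gb.start: gb.end])
        gc = seq.count("G") + seq.count("C")
        at = seq.count("A") + seq.count("T")
        denom = gc + at
        out[b] = gc / denom if denom else missing_value
    return out


def _parse_intervals(path: str | Path, bins: Sequence[GenomicBin]):
    """Yield (line_no, start, end) clipped 0-based half-open intervals on the
    bins' chromosome, handling BED (0-based half-open) vs GFF (1-based
    inclusive) by file extension."""
    path = Path(path)
    gff = path.suffix.lower() in (".gff", ".gff3", ".gtf")
    chrom = bins[0].chrom
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            try:
                if gff:
                    if len(f) < 5:
                        raise ValueError
                    c, s, e = f[0], int(f[3]) - 1, int(f[4])
                else:
                    if len(f) < 3:
                        raise ValueError
                    c, s, e = f[0], int(f[1]), int(f[2])
                if s < 0 or e <= s:
                    raise ValueError
            except ValueError:
                raise FormatError(f"{path.name} line {ln}: malformed interval") from None
            if c != chrom:
                continue
            yield ln, s, e, f


def compute_interval_track(
    annotation: str | Path, bins: Sequence[GenomicBin], mode: str = "count"
) -> np.ndarray:
    """Per-bin count of annotation intervals overlapping the bin by >= 1 bp."""
    if mode != "count":
        raise ValueError("only mode='count' is supported")
    bin_size = bins[0].end - bins[0].start
    out = np.zeros(len(bins))
    last_end = bins[-1].end
    for _, s, e, _f in _parse_intervals(annotation, bins):
        if s >= last_end:
            continue
        first = max(s // bin_size, 0)
        last = min((e - 1) // bin_size, len(bins) - 1)
        out[first: last + 1] += 1
    return out


def compute_signal_track(bedgraph: str | Path, bins: Sequence[GenomicBin]) -> np.ndarray:
    """Per-bin coverage-weighted mean bedGraph score; uncovered bases score 0.

    Overlapping bedGraph intervals are an error (ambiguous signal).
    """
    path = Path(bedgraph)
    total = np.zeros(len(bins))
    seen: list[tuple[int, int]] = []
    last_end = bins[-1].end
    bin_size = bins[0].end - bins[0].start
    for ln, s, e, f in _parse_intervals(path, bins):
        try:
            score = float(f[3])
        except (IndexError, ValueError):
            raise FormatError(f"{path.name} line {ln}: missing numeric score") from None
        for ps, pe in seen:
            if ps < e and s < pe:
                raise FormatError(f"{path.name} line {ln}: overlapping bedGraph intervals")
        seen.append((s, e))
        s_c, e_c = max(s, 0), min(e, last_end)
        pos = s_c
        while pos < e_c:
            b = pos // bin_size
            seg_end = min(e_c, (b + 1) * bin_size)
            total[b] += score * (seg_end - pos)
            pos = seg_end
    widths = np.array([b.end - b.start for b in bins], dtype=float)
    return total / widths


def read_bed_intervals(path: str | Path, chrom: str) -> list[tuple[int, int]]:
    """(start, end) intervals of one chromosome from a BED file."""
    fake_bins = [GenomicBin(chrom, 0, 1, 0)]
    return [(s, e) for _, s, e, _f in _parse_intervals(path, fake_bins)]


def read_bed_categories(path: str | Path, chrom: str) -> dict[str, list[tuple[int, int]]]:
    """Split a BED file with a category name column into interval lists."""
    out: dict[str, list[tuple[int, int]]] = {}
    fake_bins = [GenomicBin(chrom, 0, 1, 0)]
    for ln, s, e, f in _parse_intervals(path, fake_bins):
        if len(f) < 4:
            raise FormatError(f"line {ln}: category column missing")
        out.setdefault(f[3].lower(), []).append((s, e))
    return out


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_observations(
    pairs: tuple[np.ndarray, np.ndarray, np.ndarray],
    gc: np.ndarray,
    te: np.ndarray,
    acc: np.ndarray,
    bins: Sequence[GenomicBin],
    pseudocounts: dict | None = None,
) -> tuple[Observations, PairLattice]:
    """Join the dense pair enumeration with per-bin tracks.

    D is the distance in bp between bin midpoints (pseudocount * bin_size
    on the diagonal); GC/TE/ACC are the arithmetic means of the two bins'
    values floored at their pseudocounts.  Also returns the pair lattice
    over the upper triangle of the region.
    """
    pc = dict(DEFAULT_PSEUDOCOUNTS)
    if pseudocounts:
        pc.update(pseudocounts)
    i, j, y = (np.asarray(a) for a in pairs)
    m = len(bins)
    for name, track in (("GC", gc), ("TE", te), ("ACC", acc)):
        if len(track) != m:
            raise ValueError(f"{name} track covers {len(track)} bins, region has {m}")
    if i.max(initial=-1) >= m or j.max(initial=-1) >= m:
        raise ValueError("pair indices outside the bin set")
    bin_size = bins[0].end - bins[0].start
    mids = np.array([(b.start + b.end) / 2.0 for b in bins])
    D = np.abs(mids[j] - mids[i])
    D[i == j] = pc["D"] * bin_size
    gc_s = np.maximum((np.asarray(gc)[i] + np.asarray(gc)[j]) / 2.0, pc["GC"])
    te_s = np.maximum((np.asarray(te)[i] + np.asarray(te)[j]) / 2.0, pc["TE"])
    acc_s = np.maximum((np.asarray(acc)[i] + np.asarray(acc)[j]) / 2.0, pc["ACC"])
    obs = Observations(i=i.astype(np.int64), j=j.astype(np.int64), y=np.asarray(y, dtype=np.int64),
                       D=D, GC=gc_s, TE=te_s, ACC=acc_s)
    lattice = PairLattice.upper_triangle(m)
    return obs, lattice


# ---------------------------------------------------------------------------
# BEDPE output
# ---------------------------------------------------------------------------

_BEDPE_BASE = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
               "name", "score", "strand1", "strand2"]


def write_calls_bedpe(
    calls: Sequence[InteractionCall], bins: Sequence[GenomicBin], path: str | Path
) -> None:
    """Write calls as BEDPE plus per-role posterior probabilities and label.

    The score column is the posterior probability of the signal role scaled
    to [0, 1000] and rounded.
    """
    roles = {2: ("noise", "signal"), 3: ("noise", "signal", "false_signal")}
    by_index = {b.index: b for b in bins}
    rows = []
    K = len(calls[0].posterior_probs) if calls else 2
    prob_cols = [f"prob_{r}" for r in roles[K]]
    for n, c in enumerate(calls):
        if c.i not in by_index or c.j not in by_index:
            raise KeyError(f"call refers to unknown bin ({c.i}, {c.j})")
        b1, b2 = by_index[c.i], by_index[c.j]
        sig_idx = roles[K].index("signal")
        row = [b1.chrom, b1.start, b1.end, b2.chrom, b2.start, b2.end,
               f"pair_{c.i}_{c.j}", int(round(1000 * c.posterior_probs[sig_idx])), ".", "."]
        row += [f"{p:.6f}" for p in c.posterior_probs]
        row.append(c.label)
        rows.append(row)
    header = _BEDPE_BASE + prob_cols + ["label"]
    df = pd.DataFrame(rows, columns=header)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(header) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_calls_bedpe(path: str | Path, bin_size: int, threshold: float = 0.5) -> list[InteractionCall]:
    """Round-trip reader for :func:`write_calls_bedpe` output."""
    with open(path) as fh:
        header = fh.readline().lstrip("#").strip().split("\t")
        df = pd.read_csv(fh, sep="\t", names=header)
    prob_cols = [c for c in df.columns if c.startswith("prob_")]
    calls = []
    for _, r in df.iterrows():
        probs = np.array([float(r[c]) for c in prob_cols])
        probs = probs / probs.sum()
        label = str(r["label"])
        sig = label == "signal" and probs[prob_cols.index("prob_signal")] >= threshold
        calls.append(
            InteractionCall(
                i=int(r["start1"]) // bin_size, j=int(r["start2"]) // bin_size,
                posterior_probs=probs, label=label, significant=bool(sig),
            )
        )
    return calls
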