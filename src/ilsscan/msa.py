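"""Multi-species alignments: MAF input, reference-projected windows, BED output.

All coordinates are 0-based half-open on the reference (first species listed).
A genome alignment is a set of reference-sorted, non-overlapping blocks; each
block stores the gapped alignment rows for the requested species.  Windows tile
each chromosome from coordinate 0 in fixed steps of ``W`` bp; a window's
per-species sequence is the alignment row projected onto reference coordinates,
with ``-`` standing in for unaligned or deleted positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO

GAP = "-"
_BASES = frozenset(b"ACGT")


class MafParseError(ValueError):
    """Raised when a MAF file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when alignment or interval invariants are violated."""


@dataclass
class AlignmentBlock:
    """One alignment block on reference-forward coordinates.

    ``seqs`` maps species label to its gapped row; all rows have equal length,
    and the reference row's non-gap count equals the block's reference span.
    ``dup_species`` records species that appeared more than once in the source
    block (paralogous rows); windows touching such blocks are excluded.
    """

    chrom: str
    ref_start: int
    seqs: dict[str, str]
    dup_species: frozenset[str] = frozenset()

    def ref_span(self, ref: str) -> int:
        return sum(1 for ch in self.seqs[ref] if ch != GAP)

    @property
    def n_cols(self) -> int:
        return len(next(iter(self.seqs.values())))


@dataclass
class GenomeAlignment:
    """Reference-anchored multi-species alignment (reference species first)."""

    species_ids: list[str]
    blocks: list[AlignmentBlock] = field(default_factory=list)

    @property
    def ref(self) -> str:
        return self.species_ids[0]

    def validate(self) -> None:
        ref = self.ref
        last_end: dict[str, int] = {}
        for i, blk in enumerate(self.blocks):
            lens = {len(s) for s in blk.seqs.values()}
            if len(lens) != 1:
                raise ValidationError(f"block {i}: unequal row lengths {sorted(lens)}")
            if ref not in blk.seqs:
                raise ValidationError(f"block {i}: missing reference species {ref!r}")
            end = blk.ref_start + blk.ref_span(ref)
            if blk.chrom in last_end and blk.ref_start < last_end[blk.chrom]:
                raise ValidationError(
                    f"block {i}: overlapping/unsorted reference blocks on {blk.chrom}"
                )
            last_end[blk.chrom] = end

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for blk in self.blocks:
            seen.setdefault(blk.chrom, None)
        return list(seen)


@dataclass
class AlignmentWindow:
    """Fixed-size reference window with reference-projected sequences."""

    chrom: str
    start: int
    end: int
    seqs: dict[str, str]
    n_aligned_cols: int

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class WindowFilterConfig:
    """Analyzability filter for windows.

    required_species must each have a called base in at least
    ``1 - max_missing_frac`` of the window's columns, and alignment blocks must
    cover at least ``min_window_cov`` of the window.
    """

    required_species: tuple[str, ...]
    max_missing_frac: float = 0.5
    min_window_cov: float = 0.5

    def __post_init__(self) -> None:
        for name in ("max_missing_frac", "min_window_cov"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def _split_src(src: str) -> tuple[str, str]:
    """'species.chrom' -> (species, chrom); bare ids map to chrom 'chr?'."""
    if "." in src:
        sp, chrom = src.split(".", 1)
        return sp, chrom
    return src, "chr?"


def read_maf(path: str, species_ids: list[str]) -> GenomeAlignment:
    """Read a MAF file restricted to ``species_ids`` (reference listed first).

    Blocks missing the reference species are dropped; blocks are returned
    sorted by reference coordinate.  Overlapping reference blocks raise
    :class:`ValidationError`.
    """
    if not species_ids:
        raise ValueError("species_ids must be non-empty")
    ref = species_ids[0]
    wanted = set(species_ids)
    blocks: list[AlignmentBlock] = []
    with open(path) as handle:
        alignments = list(_iter_maf(handle, path))
    for bi, msa in enumerate(alignments):
        seqs: dict[str, str] = {}
        dups: set[str] = set()
        chrom = None
        ref_start = None
        for rec in msa:
            sp, rchrom = _split_src(rec.id)
            if sp not in wanted:
                continue
            if sp in seqs:
                dups.add(sp)
                continue
            seqs[sp] = str(rec.seq).upper()
            if sp == ref:
                chrom = rchrom
                ref_start = int(rec.annotations["start"])
                if int(rec.annotations.get("strand", 1)) == -1:
                    raise ValidationError(
                        f"block {bi}: reference row on minus strand not supported"
                    )
        if ref not in seqs:
            continue
        blocks.append(
            AlignmentBlock(
                chrom=chrom, ref_start=ref_start, seqs=seqs, dup_species=frozenset(dups)
            )
        )
    blocks.sort(key=lambda b: (b.chrom, b.ref_start))
    ga = GenomeAlignment(species_ids=list(species_ids), blocks=blocks)
    ga.validate()
    return ga


def _iter_maf(handle, path):
    """Iterate MAF alignments, re-raising parse failures with context."""
    it = AlignIO.parse(handle, "maf")
    idx = 0
    while True:
        try:
            msa = next(it)
        except StopIteration:
            return
        except ValueError as exc:  # malformed record
            raise MafParseError(f"{path}: malformed MAF near block {idx}: {exc}") from exc
        yield msa
        idx += 1


def read_fasta_alignment(
    path: str, species_ids: list[str], chrom: str = "chr?", ref_start: int = 0
) -> GenomeAlignment:
    """Read one aligned multi-FASTA (record ids = species labels) as one block."""
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
    missing = [s for s in species_ids if s not in seqs]
    if missing:
        raise ValidationError(f"{path}: missing species {missing}")
    blk = AlignmentBlock(chrom=chrom, ref_start=ref_start,
                         seqs={s: seqs[s] for s in species_ids})
    ga = GenomeAlignment(species_ids=list(species_ids), blocks=[blk])
    ga.validate()
    return ga


def _project_chrom(
    ga: GenomeAlignment, chrom: str, length: int
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Project gapped rows onto reference coordinates [0, length).

    Returns per-species uint8 arrays (gap byte where unaligned) and a boolean
    mask of positions covered by a block containing a duplicated species row.
    """
    gap_byte = ord(GAP)
    arrays = {
        sp: np.full(length, gap_byte, dtype=np.uint8) for sp in ga.species_ids
    }
    dup_mask = np.zeros(length, dtype=bool)
    ref = ga.ref
    for blk in ga.blocks:
        if blk.chrom != chrom:
            continue
        refrow = np.frombuffer(blk.seqs[ref].encode(), dtype=np.uint8)
        is_base = refrow != gap_byte
        ncols = int(is_base.sum())
        pos = blk.ref_start + np.arange(ncols)
        keep = pos < length
        if not keep.any():
            continue
        cols = np.flatnonzero(is_base)[keep]
        pos = pos[keep]
        for sp in ga.species_ids:
            row = blk.seqs.get(sp)
            if row is None:
                continue
            arr = np.frombuffer(row.encode(), dtype=np.uint8)
            arrays[sp][pos] = arr[cols]
        if blk.dup_species:
            dup_mask[pos] = True
    return arrays, dup_mask


def _chrom_length(ga: GenomeAlignment, chrom: str) -> int:
    ref = ga.ref
    return max(
        (b.ref_start + b.ref_span(ref) for b in ga.blocks if b.chrom == chrom),
        default=0,
    )


def extract_windows_with_manifest(
    ga: GenomeAlignment, window_size: int, filt: WindowFilterConfig
) -> tuple[list[AlignmentWindow], pd.DataFrame]:
    """Tile each chromosome into windows of ``window_size`` and apply ``filt``.

    Windows are anchored at multiples of ``window_size`` from coordinate 0;
    the partial terminal window is discarded.  The manifest records every tiled
    window with pass/fail status and the failure reason.
    """
    if window_size <= 0:
        raise ValueError(f"window_size must be positive, got {window_size}")
    ga.validate()
    W = window_size
    gap_byte = ord(GAP)
    base_bytes = np.zeros(256, dtype=bool)
    for b in _BASES:
        base_bytes[b] = True

    windows: list[AlignmentWindow] = []
    rows: list[dict] = []
    for chrom in ga.chroms():
        L = _chrom_length(ga, chrom)
        n_win = L // W
        if n_win == 0:
            continue
        arrays, dup_mask = _project_chrom(ga, chrom, n_win * W)
        mats = {sp: arrays[sp].reshape(n_win, W) for sp in ga.species_ids}
        has_base = {
            sp: base_bytes[mats[sp]] for sp in filt.required_species
        }
        all_base = np.ones((n_win, W), dtype=bool)
        for m in has_base.values():
            all_base &= m
        n_aligned = all_base.sum(axis=1)
        cov = (mats[ga.ref].reshape(n_win, W) != gap_byte).mean(axis=1)
        dup_any = dup_mask.reshape(n_win, W).any(axis=1)
        missing_frac = {
            sp: 1.0 - has_base[sp].mean(axis=1) for sp in filt.required_species
        }
        for i in range(n_win):
            start, end = i * W, (i + 1) * W
            reason = ""
            if dup_any[i]:
                reason = "duplicate_rows"
            elif cov[i] < filt.min_window_cov:
                reason = "low_coverage"
            else:
                for sp in filt.required_species:
                    if missing_frac[sp][i] > filt.max_missing_frac:
                        reason = f"missing:{sp}"
                        break
            ok = reason == ""
            rows.append(
                dict(chrom=chrom, start=start, end=end,
                     n_aligned_cols=int(n_aligned[i]),
                     status="pass" if ok else "fail", reason=reason)
            )
            if ok:
                windows.append(
                    AlignmentWindow(
                        chrom=chrom, start=start, end=end,
                        seqs={sp: mats[sp][i].tobytes().decode() for sp in ga.species_ids},
                        n_aligned_cols=int(n_aligned[i]),
                    )
                )
    manifest = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_aligned_cols", "status", "reason"]
    )
    return windows, manifest


def extract_windows(
    ga: GenomeAlignment, window_size: int, filt: WindowFilterConfig
) -> list[AlignmentWindow]:
    """Windows passing the analyzability filter (see extract_windows_with_manifest)."""
    return extract_windows_with_manifest(ga, window_size, filt)[0]


def _as_interval(item) -> tuple[str, int, int, str]:
    if isinstance(item, AlignmentWindow):
        return item.chrom, item.start, item.end, "."
    chrom, start, end = item[0], int(item[1]), int(item[2])
    name = str(item[3]) if len(item) > 3 else "."
    return chrom, start, end, name


def write_bed(intervals, path: str, label_field: str = "name") -> None:
    """Write intervals as 0-based half-open BED with a name column.

    Input must be sorted within each chromosome; round-trips through
    :func:`read_bed`.
    """
    recs = [_as_interval(it) for it in intervals]
    last: dict[str, int] = {}
    for chrom, start, end, _ in recs:
        if chrom in last and start < last[chrom]:
            raise ValidationError(f"unsorted intervals on {chrom}")
        last[chrom] = start
    with open(path, "w") as fh:
        fh.write(f"#chrom\tstart\tend\t{label_field}\n")
        for chrom, start, end, name in recs:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_bed(path: str) -> list[tuple[str, int, int, str]]:
    """Read a BED file written by :func:`write_bed` (comments ignored)."""
    out: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else "."
            out.append((parts[0], int(parts[1]), int(parts[2]), name))
    return out


def write_maf(ga: GenomeAlignment, path: str) -> None:
    """Write a GenomeAlignment as MAF (forward strand, srcSize = block extent)."""
    ref = ga.ref
    with open(path, "w") as fh:
        fh.write("##maf version=1 scoring=none\n")
        for blk in ga.blocks:
            fh.write("a score=0.0\n")
            span = blk.ref_span(ref)
            src_size = blk.ref_start + span
            for sp in ga.species_ids:
                row = blk.seqs.get(sp)
                if row is None:
                    continue
                n_nongap = sum(1 for ch in row if ch != GAP)
                start = blk.ref_start if sp == ref else 0
                size = span if sp == ref else n_nongap
                total = src_size if sp == ref else n_nongap
                fh.write(
                    f"s {sp}.{blk.chrom} {start} {size} + {total} {row}\n"
                )
            fh.write("\n")
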