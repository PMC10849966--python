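"""Aligned-fragment I/O, filtering, duplicate removal and pileups.

Ancient-DNA mitochondrial fragments are short merged single-end molecules
aligned against a circular reference.  This module reads them from SAM,
applies the standard fragment filters (minimum length 35 bp, minimum
mapping quality 25), collapses PCR duplicates by their
(start, end, strand) key, and aggregates per-site base counts, optionally
with an observation-level mask (used downstream to ignore terminal
deamination).

Coordinates are 0-based internally; reports use 1-based mtDNA (rCRS-style)
positions.  Fragments that span the circular origin are represented with
reference positions taken modulo the reference length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pysam

from ._seq import N, decode, encode

logger = logging.getLogger(__name__)

#: SAM @CO line declaring the circular-origin convention used by the writer.
CIRCULAR_COMMENT = (
    "circular reference: alignments may extend past LN; "
    "reference positions wrap modulo LN"
)


@dataclass
class AlignedFragment:
    """One aligned ancient DNA fragment.

    ``observations`` are stored as three parallel arrays sorted along the
    fragment's (possibly origin-wrapping) reference interval:

    - ``obs_ref_pos``: 0-based reference coordinate (already modulo L),
    - ``obs_read_pos``: 0-based position from the read's 5' end in read
      orientation,
    - ``obs_base``: base observed in *reference* orientation, uint8-coded.
    """

    id: str
    ref_start: int
    strand: str  # '+' or '-'
    mapq: int
    read_length: int
    obs_ref_pos: np.ndarray
    obs_read_pos: np.ndarray
    obs_base: np.ndarray
    ref_span: int = 0  # reference bases consumed by the alignment
    read_seq: str | None = None  # full read in read orientation, if known

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.ref_span == 0:
            self.ref_span = len(self.obs_ref_pos)

    @property
    def ref_end(self) -> int:
        """Unwrapped exclusive end coordinate (may exceed reference length)."""
        return self.ref_start + self.ref_span

    @property
    def n_obs(self) -> int:
        return len(self.obs_ref_pos)

    def observations(self) -> Iterable[tuple[int, int, str]]:
        """Yield (ref_pos, read_pos_from_5prime, base) tuples."""
        for r, q, b in zip(self.obs_ref_pos, self.obs_read_pos, self.obs_base):
            yield int(r), int(q), decode(np.array([b], dtype=np.uint8))


@dataclass
class SitePileup:
    """Per-site base counts before and after masking."""

    position: int  # 0-based
    counts_raw: dict[str, int]
    counts_masked: dict[str, int]
    n_fragments: int


@dataclass
class SamReadStats:
    n_mapped: int = 0
    n_unmapped_skipped: int = 0


# CIGAR op codes (pysam): M=0 I=1 D=2 N=3 S=4 H=5 P=6 ==7 X=8
_CONSUME_BOTH = {0, 7, 8}
_CONSUME_QUERY = {1, 4}
_CONSUME_REF = {2, 3}


def _fragment_from_record(rec: pysam.AlignedSegment, ref_length: int) -> AlignedFragment:
    seq = rec.query_sequence
    if seq is None:
        raise ValueError(f"record {rec.query_name!r} has no sequence")
    read_length = len(seq)
    bases = encode(seq)
    qpos = 0
    rpos = rec.reference_start
    ref_positions: list[np.ndarray] = []
    read_positions: list[np.ndarray] = []
    obs_bases: list[np.ndarray] = []
    ref_consumed = 0
    cig = rec.cigartuples
    if cig is None:
        raise ValueError(f"record {rec.query_name!r} has no CIGAR")
    for op, length in cig:
        if op in _CONSUME_BOTH:
            k = np.arange(length)
            ref_positions.append((rpos + k) % ref_length)
            read_positions.append(qpos + k)
            obs_bases.append(bases[qpos : qpos + length])
            qpos += length
            rpos += length
            ref_consumed += length
        elif op in _CONSUME_QUERY:
            qpos += length
        elif op in _CONSUME_REF:
            rpos += length
            ref_consumed += length
        elif op == 5 or op == 6:  # H, P: consume nothing
            continue
        else:
            raise ValueError(
                f"record {rec.query_name!r}: unsupported CIGAR op code {op}"
            )
    obs_ref = np.concatenate(ref_positions) if ref_positions else np.empty(0, int)
    obs_read = np.concatenate(read_positions) if read_positions else np.empty(0, int)
    obs_base = (
        np.concatenate(obs_bases) if obs_bases else np.empty(0, np.uint8)
    )
    strand = "-" if rec.is_reverse else "+"
    if strand == "-":
        # SAM stores SEQ in reference orientation; read coordinates from the
        # molecule's 5' end run opposite to reference order.
        obs_read = read_length - 1 - obs_read
    return AlignedFragment(
        id=rec.query_name or "",
        ref_start=rec.reference_start % ref_length,
        strand=strand,
        mapq=rec.mapping_quality,
        read_length=read_length,
        obs_ref_pos=obs_ref,
        obs_read_pos=obs_read,
        obs_base=obs_base,
        ref_span=ref_consumed,
        read_seq=None,
    )


def read_sam(
    path,
    ref,
    with_stats: bool = False,
) -> list[AlignedFragment] | tuple[list[AlignedFragment], SamReadStats]:
    """Read aligned fragments from a SAM file.

    ``ref`` is a ReferenceGenome (or any object with ``name`` and
    ``sequence``); the @SQ line must match its name and length.  Unmapped
    records are skipped and counted.  Reference positions of alignments
    extending past the reference end are wrapped modulo its length (see
    :data:`CIRCULAR_COMMENT`).
    """
    ref_length = len(ref.sequence)
    stats = SamReadStats()
    fragments: list[AlignedFragment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        sq = {name: fh.get_reference_length(name) for name in fh.references}
        if ref.name not in sq:
            raise ValueError(
                f"SAM header @SQ does not contain reference {ref.name!r}"
            )
        if sq[ref.name] != ref_length:
            raise ValueError(
                f"@SQ length {sq[ref.name]} != reference length {ref_length}"
            )
        for i, rec in enumerate(fh):
            if rec.is_unmapped:
                stats.n_unmapped_skipped += 1
                continue
            try:
                fragments.append(_fragment_from_record(rec, ref_length))
            except ValueError as exc:
                raise ValueError(f"SAM record {i + 1}: {exc}") from exc
            stats.n_mapped += 1
    if stats.n_unmapped_skipped:
        logger.info("read_sam: skipped %d unmapped records", stats.n_unmapped_skipped)
    if with_stats:
        return fragments, stats
    return fragments


def filter_fragments(
    fragments: Sequence[AlignedFragment],
    min_length: int = 35,
    min_mapq: int = 25,
) -> list[AlignedFragment]:
    """Remove fragments shorter than ``min_length`` or with mapping quality
    below ``min_mapq`` (strict removal: length >= 35 and MQ >= 25 are kept).

    Order is preserved; per-criterion removal counts are logged.
    """
    kept: list[AlignedFragment] = []
    n_short = n_lowmq = 0
    for f in fragments:
        short = f.read_length < min_length
        lowmq = f.mapq < min_mapq
        n_short += short
        n_lowmq += lowmq
        if not short and not lowmq:
            kept.append(f)
    logger.info(
        "filter_fragments: removed %d short (<%d bp), %d low-MQ (<%d); kept %d/%d",
        n_short, min_length, n_lowmq, min_mapq, len(kept), len(fragments),
    )
    return kept


def _majority_base(stack: np.ndarray) -> np.ndarray:
    """Column-wise majority base over a (k, m) stack of base codes.

    N observations are ignored; ties for the top base give N.
    """
    k, m = stack.shape
    counts = np.zeros((5, m), dtype=np.int64)
    for row in stack:
        np.add.at(counts, (row, np.arange(m)), 1)
    acgt = counts[:4]
    top = acgt.max(axis=0)
    winner = acgt.argmax(axis=0).astype(np.uint8)
    tie = (acgt == top[None, :]).sum(axis=0) > 1
    out = np.where((top == 0) | tie, np.uint8(N), winner)
    return out.astype(np.uint8)


def deduplicate(fragments: Sequence[AlignedFragment]) -> list[AlignedFragment]:
    """Collapse PCR duplicates sharing (ref_start, ref_end, strand).

    The representative keeps the first duplicate's identity and carries the
    per-position majority base among duplicates (ties become N).  Groups
    whose members disagree in alignment structure (different observation
    layout, e.g. indels) fall back to keeping the first member.
    """
    groups: dict[tuple[int, int, str], list[AlignedFragment]] = {}
    order: list[tuple[int, int, str]] = []
    for f in fragments:
        key = (f.ref_start, f.ref_span, f.strand)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(f)

    out: list[AlignedFragment] = []
    n_collapsed = 0
    for key in order:
        members = groups[key]
        rep = members[0]
        if len(members) == 1:
            out.append(rep)
            continue
        n_collapsed += len(members) - 1
        same_layout = all(
            m.n_obs == rep.n_obs and np.array_equal(m.obs_ref_pos, rep.obs_ref_pos)
            for m in members[1:]
        )
        if not same_layout:
            logger.warning(
                "deduplicate: group %s has inconsistent layouts; keeping first", key
            )
            out.append(rep)
            continue
        stack = np.stack([m.obs_base for m in members])
        consensus = _majority_base(stack)
        out.append(
            AlignedFragment(
                id=rep.id,
                ref_start=rep.ref_start,
                strand=rep.strand,
                mapq=max(m.mapq for m in members),
                read_length=rep.read_length,
                obs_ref_pos=rep.obs_ref_pos,
                obs_read_pos=rep.obs_read_pos,
                obs_base=consensus,
                ref_span=rep.ref_span,
                read_seq=None,
            )
        )
    logger.info(
        "deduplicate: %d fragments -> %d (collapsed %d duplicates)",
        len(fragments), len(out), n_collapsed,
    )
    return out


def pileup_matrix(
    fragments: Sequence[AlignedFragment],
    ref,
    mask_fn: Callable[[AlignedFragment], np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate observations into (L, 4) base-count matrices.

    Returns ``(counts_raw, counts_masked)``.  ``mask_fn`` maps a fragment to
    a boolean array over its observations; True means *exclude* from the
    masked counts.  N observations are never counted.
    """
    L = len(ref.sequence)
    raw = np.zeros((L, 4), dtype=np.int64)
    masked = np.zeros((L, 4), dtype=np.int64)
    for f in fragments:
        keep = f.obs_base < 4
        pos = f.obs_ref_pos[keep]
        base = f.obs_base[keep]
        np.add.at(raw, (pos, base), 1)
        if mask_fn is None:
            np.add.at(masked, (pos, base), 1)
        else:
            excl = np.asarray(mask_fn(f), dtype=bool)
            keep2 = keep & ~excl
            np.add.at(masked, (f.obs_ref_pos[keep2], f.obs_base[keep2]), 1)
    return raw, masked


_BASE_NAMES = "ACGT"


def pileup(
    fragments: Sequence[AlignedFragment],
    ref,
    mask_fn: Callable[[AlignedFragment], np.ndarray] | None = None,
    zero_fill: bool = False,
) -> list[SitePileup]:
    """Per-site pileups; zero-coverage sites are omitted unless ``zero_fill``."""
    raw, masked = pileup_matrix(fragments, ref, mask_fn)
    cov = raw.sum(axis=1)
    positions = np.arange(len(cov)) if zero_fill else np.nonzero(cov)[0]
    return [
        SitePileup(
            position=int(p),
            counts_raw={b: int(raw[p, i]) for i, b in enumerate(_BASE_NAMES)},
            counts_masked={b: int(masked[p, i]) for i, b in enumerate(_BASE_NAMES)},
            n_fragments=int(cov[p]),
        )
        for p in positions
    ]
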