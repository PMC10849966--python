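"""Damage-masked consensus calling for ancient mtDNA genomes.

A site is called only when, after removing putatively deaminated terminal
observations, at least ``min_coverage`` fragments cover it and the top
base reaches ``min_support`` of the masked coverage (support exactly at
the threshold passes; a tie for the top base gives N).  The mask discards
read-orientation C→T observations (template C, read T; on minus-strand
records that is reference G read A) within ``mask_window`` positions of
either alignment end — unconditionally, so a genuine terminal T allele at
a C reference site is masked too.

For libraries whose present-day contamination estimate exceeds the
``contamination_threshold`` (default 5%), only deaminated fragments are
used, since contaminant molecules carry no terminal damage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import A, C, G, N, T, decode, encode
from .alignment import AlignedFragment, pileup_matrix
from .damage import ContaminationEstimate

logger = logging.getLogger(__name__)

ALL_FRAGMENTS = "all_fragments"
DEAMINATED_ONLY = "deaminated_only"


@dataclass
class ConsensusParams:
    min_coverage: int = 5
    min_support: float = 0.80
    mask_window: int = 7
    mode: str = ALL_FRAGMENTS
    contamination_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not 0.5 < self.min_support <= 1.0:
            raise ValueError("min_support must be in (0.5, 1]")
        if self.mask_window < 0:
            raise ValueError("mask_window must be >= 0")
        if self.mode not in (ALL_FRAGMENTS, DEAMINATED_ONLY):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class ConsensusGenome:
    sequence: str
    coverage_masked: np.ndarray
    top_base: np.ndarray  # uint8 codes; N where no observation
    support: np.ndarray  # top_count / coverage_masked; NaN at zero coverage
    called: np.ndarray  # bool
    mode_used: str
    params: ConsensusParams

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_called(self) -> int:
        return int(self.called.sum())

    @property
    def n_missing(self) -> int:
        return len(self.sequence) - self.n_called

    def summary(self) -> dict:
        return {
            "n_called": self.n_called,
            "n_N": self.n_missing,
            "mode": self.mode_used,
            "params": {
                "min_coverage": self.params.min_coverage,
                "min_support": self.params.min_support,
                "mask_window": self.params.mask_window,
                "contamination_threshold": self.params.contamination_threshold,
            },
        }


def select_mode(
    contamination: ContaminationEstimate | float, threshold: float = 0.05
) -> str:
    """All fragments below the contamination threshold, deaminated-only at
    or above it (the boundary resolves to the conservative branch)."""
    point = (
        contamination.point
        if isinstance(contamination, ContaminationEstimate)
        else float(contamination)
    )
    return ALL_FRAGMENTS if point < threshold else DEAMINATED_ONLY


def terminal_damage_mask(
    fragment: AlignedFragment, ref, window: int = 7
) -> np.ndarray:
    """Boolean exclusion mask over a fragment's observations.

    True where the observation is a read-orientation C→T within ``window``
    positions of either read end: plus strand — reference C, read T;
    minus strand — reference G, read A.
    """
    ref_codes = ref.encoded if hasattr(ref, "encoded") else ref
    tmpl = ref_codes[fragment.obs_ref_pos]
    base = fragment.obs_base
    if fragment.strand == "+":
        is_ct = (tmpl == C) & (base == T)
    else:
        is_ct = (tmpl == G) & (base == A)
    pos5 = fragment.obs_read_pos
    pos3 = fragment.read_length - 1 - fragment.obs_read_pos
    return is_ct & ((pos5 < window) | (pos3 < window))


def mask_terminal_damage(
    observation: tuple[int, int, str],
    fragment: AlignedFragment,
    ref,
    window: int = 7,
) -> bool:
    """Scalar form of :func:`terminal_damage_mask` for one
    (ref_pos, read_pos_from_5prime, base) observation."""
    ref_pos, read_pos, base = observation
    ref_codes = ref.encoded if hasattr(ref, "encoded") else ref
    b = int(encode(base)[0])
    t = int(ref_codes[ref_pos])
    if fragment.strand == "+":
        is_ct = t == C and b == T
    else:
        is_ct = t == G and b == A
    pos3 = fragment.read_length - 1 - read_pos
    return is_ct and (read_pos < window or pos3 < window)


def call_consensus(
    fragments: Sequence[AlignedFragment],
    ref,
    params: ConsensusParams | None = None,
    deaminated_flags: np.ndarray | None = None,
) -> ConsensusGenome:
    """Call the consensus genome under coverage/support/masking rules.

    In ``deaminated_only`` mode only fragments flagged True in
    ``deaminated_flags`` (aligned with ``fragments``) contribute.
    """
    params = params or ConsensusParams()
    L = len(ref.sequence)
    if params.mode == DEAMINATED_ONLY:
        if deaminated_flags is None:
            raise ValueError("deaminated_only mode requires deaminated_flags")
        if len(deaminated_flags) != len(fragments):
            raise ValueError("deaminated_flags length mismatch")
        fragments = [f for f, keep in zip(fragments, deaminated_flags) if keep]

    ref_codes = ref.encoded
    _, masked = pileup_matrix(
        fragments, ref, mask_fn=lambda f: terminal_damage_mask(f, ref_codes, params.mask_window)
    )
    cov = masked.sum(axis=1)
    top_count = masked.max(axis=1)
    top_idx = masked.argmax(axis=1).astype(np.uint8)
    tie = (masked == top_count[:, None]).sum(axis=1) > 1
    with np.errstate(invalid="ignore", divide="ignore"):
        support = np.where(cov > 0, top_count / np.maximum(cov, 1), np.nan)
    # support threshold is inclusive; the epsilon keeps exact-fraction cases
    # (e.g. 8/10 at 0.80) from failing on float rounding
    passes_support = np.where(
        cov > 0, top_count / np.maximum(cov, 1) >= params.min_support - 1e-12, False
    )
    called = (cov >= params.min_coverage) & ~tie & passes_support

    seq_codes = np.where(called, top_idx, np.uint8(N)).astype(np.uint8)
    top_base = np.where((cov > 0) & ~tie, top_idx, np.uint8(N)).astype(np.uint8)
    logger.info(
        "call_consensus: mode=%s called %d/%d sites from %d fragments",
        params.mode, int(called.sum()), L, len(fragments),
    )
    return ConsensusGenome(
        sequence=decode(seq_codes),
        coverage_masked=cov,
        top_base=top_base,
        support=support,
        called=called,
        mode_used=params.mode,
        params=params,
    )


def write_consensus(
    genome: ConsensusGenome, fasta_path, tsv_path=None, name: str = "consensus"
) -> None:
    """FASTA (single record) plus optional per-site TSV (1-based positions)."""
    from .simulate import write_fasta  # local import to avoid cycle

    write_fasta({name: genome.sequence}, fasta_path)
    if tsv_path is not None:
        df = pd.DataFrame(
            {
                "position": np.arange(1, len(genome) + 1),
                "call": list(genome.sequence),
                "coverage_masked": genome.coverage_masked,
                "top_base": list(decode(genome.top_base)),
                "support": genome.support,
                "called": genome.called.astype(int),
            }
        )
        df.to_csv(tsv_path, sep="\t", index=False, float_format="%.4f")


def write_consensus_summary(genome: ConsensusGenome, path) -> None:
    with open(path, "w") as fh:
        json.dump(genome.summary(), fh, indent=2)
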