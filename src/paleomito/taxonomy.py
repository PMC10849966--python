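"""Hominin mtDNA lineage assignment from diagnostic positions.

A diagnostic position is an mtDNA site whose base state differs between
H. sapiens, Neanderthal and/or Denisovan mitochondrial lineages.  Each
fragment observation at such a site is tallied to the lineage(s) whose
state it matches; the verdict goes to the lineage that wins every pairwise
contrast by a configurable margin.  With damage-aware exclusion enabled,
observations that deamination could have manufactured from the competing
state (a read-orientation C→T near a fragment end) are discarded before
tallying, so heavily damaged fragments do not masquerade as the T-bearing
lineage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import C, T, complement, encode
from .alignment import AlignedFragment

logger = logging.getLogger(__name__)

LINEAGES = ("sapiens", "neanderthal", "denisovan")
_BASE_COLS = {lin: f"base_{lin}" for lin in LINEAGES}


@dataclass
class DiagnosticTable:
    """Validated table of diagnostic positions (1-based coordinates)."""

    df: pd.DataFrame  # columns: position, base_sapiens, base_neanderthal, base_denisovan

    def __post_init__(self) -> None:
        required = ["position"] + list(_BASE_COLS.values())
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"diagnostic table missing columns: {missing}")
        if len(self.df) == 0:
            return
        dup = self.df["position"][self.df["position"].duplicated()]
        if len(dup):
            raise ValueError(
                f"duplicate diagnostic position(s): {sorted(dup.unique().tolist())}"
            )
        for col in _BASE_COLS.values():
            bad = ~self.df[col].astype(str).str.upper().isin(list("ACGT"))
            if bad.any():
                raise ValueError(f"invalid base state(s) in column {col}")
        states = self.df[list(_BASE_COLS.values())].apply(
            lambda r: len(set(r.str.upper())), axis=1
        )
        flat = self.df["position"][states == 1]
        if len(flat):
            raise ValueError(
                "non-diagnostic row(s) (all lineage states equal) at position(s): "
                f"{sorted(flat.tolist())}"
            )

    def __len__(self) -> int:
        return len(self.df)

    def informative_for(self, position: int) -> set[tuple[str, str]]:
        """Lineage pairs whose states differ at a 1-based position."""
        row = self.df.loc[self.df["position"] == position].iloc[0]
        pairs = set()
        for a, b in combinations(LINEAGES, 2):
            if row[_BASE_COLS[a]].upper() != row[_BASE_COLS[b]].upper():
                pairs.add((a, b))
        return pairs

    def state_arrays(self) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """(0-based positions, {lineage: encoded state}) sorted by position."""
        df = self.df.sort_values("position")
        pos0 = df["position"].to_numpy(dtype=int) - 1
        states = {
            lin: encode("".join(df[_BASE_COLS[lin]].str.upper())) for lin in LINEAGES
        }
        return pos0, states


@dataclass
class LineageAssignment:
    """Per-lineage diagnostic support and the resulting verdict."""

    n_support: dict[str, int]
    pair_counts: dict[tuple[str, str], tuple[int, int]]
    pair_fractions: dict[tuple[str, str], float]
    n_informative: int
    n_sites_covered: int
    n_excluded_damage: int
    verdict: str  # lineage name or 'unassigned'

    @property
    def support_fraction(self) -> dict[str, float]:
        """Each lineage's worst pairwise support fraction (NaN if no contrast)."""
        out = {}
        for lin in LINEAGES:
            fracs = [
                f if pair[0] == lin else 1 - f
                for pair, f in self.pair_fractions.items()
                if lin in pair and not np.isnan(f)
            ]
            out[lin] = min(fracs) if fracs else float("nan")
        return out

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "n_support": self.n_support,
            "support_fraction": self.support_fraction,
            "pair_counts": {f"{a}|{b}": list(v) for (a, b), v in self.pair_counts.items()},
            "n_informative": self.n_informative,
            "n_sites_covered": self.n_sites_covered,
            "n_excluded_damage": self.n_excluded_damage,
        }


def read_diagnostic_table(path) -> DiagnosticTable:
    """Read and validate a diagnostic-position TSV (header required)."""
    df = pd.read_csv(path, sep="\t")
    return DiagnosticTable(df)


def write_diagnostic_table(table: DiagnosticTable | pd.DataFrame, path) -> None:
    df = table.df if isinstance(table, DiagnosticTable) else table
    df.to_csv(path, sep="\t", index=False)


def assign_lineage(
    fragments: Sequence[AlignedFragment],
    table: DiagnosticTable,
    damage_aware: bool = True,
    min_obs: int = 10,
    min_margin: float = 0.8,
    mask_window: int = 7,
) -> LineageAssignment:
    """Tally fragment observations at diagnostic positions and call a lineage.

    For each observation at a diagnostic site, the base (converted to read
    orientation for minus-strand fragments, as are the lineage states) is
    matched against each lineage's state.  Under ``damage_aware``, an
    observed read-orientation T within ``mask_window`` positions of either
    read end is excluded whenever any lineage state at the site is C —
    deamination from that state could have produced the T.

    The verdict is the lineage that wins every pairwise contrast it appears
    in with fraction >= ``min_margin``, provided >= ``min_obs`` informative
    observations were seen in total; otherwise 'unassigned'.
    """
    if len(table) == 0:
        raise ValueError("empty diagnostic table")
    pos0, states = table.state_arrays()
    site_index = {int(p): k for k, p in enumerate(pos0)}
    n_sites = len(pos0)

    # matches[lin][k]: observations at site k equal to lin's state
    matches = {lin: np.zeros(n_sites, dtype=np.int64) for lin in LINEAGES}
    covered = np.zeros(n_sites, dtype=bool)
    n_excluded = 0
    n_informative = 0

    for frag in fragments:
        hit = np.isin(frag.obs_ref_pos, pos0)
        if not hit.any():
            continue
        obs_pos = frag.obs_ref_pos[hit]
        obs_base = frag.obs_base[hit]
        obs_read = frag.obs_read_pos[hit]
        if frag.strand == "-":
            obs_base_ro = complement(obs_base)
        else:
            obs_base_ro = obs_base
        pos3 = frag.read_length - 1 - obs_read
        terminal = (obs_read < mask_window) | (pos3 < mask_window)
        for j in range(len(obs_pos)):
            k = site_index[int(obs_pos[j])]
            b = obs_base_ro[j]
            if b >= 4:
                continue
            site_states_ro = {}
            for lin in LINEAGES:
                s = states[lin][k]
                site_states_ro[lin] = complement(np.array([s], np.uint8))[0] if frag.strand == "-" else s
            if (
                damage_aware
                and b == T
                and terminal[j]
                and any(s == C for s in site_states_ro.values())
            ):
                n_excluded += 1
                continue
            matched = [lin for lin in LINEAGES if site_states_ro[lin] == b]
            if not matched or len(matched) == len(LINEAGES):
                continue
            covered[k] = True
            n_informative += 1
            for lin in matched:
                matches[lin][k] += 1

    pair_counts: dict[tuple[str, str], tuple[int, int]] = {}
    pair_fractions: dict[tuple[str, str], float] = {}
    for a, b in combinations(LINEAGES, 2):
        differs = states[a] != states[b]
        n_a = int(matches[a][differs].sum())
        n_b = int(matches[b][differs].sum())
        pair_counts[(a, b)] = (n_a, n_b)
        pair_fractions[(a, b)] = n_a / (n_a + n_b) if n_a + n_b else float("nan")

    verdict = "unassigned"
    if n_informative >= min_obs:
        for lin in LINEAGES:
            wins = []
            for (a, b), frac in pair_fractions.items():
                if lin not in (a, b) or np.isnan(frac):
                    continue
                f = frac if a == lin else 1 - frac
                wins.append(f >= min_margin)
            if wins and all(wins):
                verdict = lin
                break

    n_support = {lin: int(matches[lin].sum()) for lin in LINEAGES}
    logger.info(
        "assign_lineage: verdict=%s informative=%d excluded_damage=%d",
        verdict, n_informative, n_excluded,
    )
    return LineageAssignment(
        n_support=n_support,
        pair_counts=pair_counts,
        pair_fractions=pair_fractions,
        n_informative=n_informative,
        n_sites_covered=int(covered.sum()),
        n_excluded_damage=n_excluded,
        verdict=verdict,
    )
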