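"""Terminal deamination quantification and damage-based contamination estimation.

Post-mortem cytosine deamination is read as C→T in read orientation,
concentrated at fragment ends; it is the primary authenticity signal for
ancient DNA.  This module measures position-wise terminal C→T frequencies
(with Wilson confidence intervals), flags individual fragments as
deaminated, and estimates the present-day contaminant fraction with a
conditional-damage mixture estimator.

The estimator assumes (i) contaminant fragments are undamaged and (ii)
deamination at the two ends of an endogenous fragment is independent.
Writing r for the endogenous per-opportunity terminal C→T rate, eps' =
error_rate/3 for the error floor, and c for the contaminant fraction, the
observed 5' terminal rate over all fragments is p_terminal ≈ (1-c)·r + eps',
while the same rate over fragments that carry at least one 3' terminal C→T
(an almost purely endogenous subset) is p_conditional ≈ r + eps'.  Hence
c = 1 - (p_terminal - eps') / (p_conditional - eps').
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from ._seq import C, T, complement
from .alignment import AlignedFragment

logger = logging.getLogger(__name__)


class ContaminationUndefinedError(RuntimeError):
    """Raised when the damage signal is too weak to support an estimate."""


@dataclass
class DamageProfile:
    """Position-indexed terminal C→T substitution frequencies.

    Arrays are indexed by distance (0-based) from the respective read end,
    in read orientation.  ``ct5[i]`` = substitutions / opportunities at
    position i from the 5' end; NaN where there were no opportunities.
    """

    window: int
    ct5: np.ndarray
    ct3: np.ndarray
    sub5: np.ndarray
    sub3: np.ndarray
    opp5: np.ndarray
    opp3: np.ndarray
    ci5_low: np.ndarray
    ci5_high: np.ndarray
    ci3_low: np.ndarray
    ci3_high: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table, 1-based positions, one row per (end, position)."""
        rows = []
        for end, sub, opp, freq, lo, hi in (
            ("5p", self.sub5, self.opp5, self.ct5, self.ci5_low, self.ci5_high),
            ("3p", self.sub3, self.opp3, self.ct3, self.ci3_low, self.ci3_high),
        ):
            for i in range(self.window):
                rows.append(
                    {
                        "end": end,
                        "position": i + 1,
                        "substitutions": int(sub[i]),
                        "opportunities": int(opp[i]),
                        "freq": float(freq[i]),
                        "ci_low": float(lo[i]),
                        "ci_high": float(hi[i]),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class ContaminationEstimate:
    point: float
    ci_low: float
    ci_high: float
    p_terminal: float
    p_conditional: float
    n_conditioning: int
    n_fragments: int
    n_boot: int
    seed: int


def _read_orientation_arrays(
    frag: AlignedFragment, ref_codes: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Template base, read base (both read orientation), and distances from
    the 5' and 3' read ends, for every observation of ``frag``."""
    tmpl = ref_codes[frag.obs_ref_pos]
    base = frag.obs_base
    if frag.strand == "-":
        tmpl = complement(tmpl)
        base = complement(base)
    pos5 = frag.obs_read_pos
    pos3 = frag.read_length - 1 - frag.obs_read_pos
    return tmpl, base, pos5, pos3


def _stack_observations(
    fragments: Sequence[AlignedFragment], ref_codes: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    tmpls, bases, p5s, p3s = [], [], [], []
    for f in fragments:
        t, b, p5, p3 = _read_orientation_arrays(f, ref_codes)
        tmpls.append(t)
        bases.append(b)
        p5s.append(p5)
        p3s.append(p3)
    cat = lambda xs, dt: (np.concatenate(xs) if xs else np.empty(0, dt))
    return (
        cat(tmpls, np.uint8),
        cat(bases, np.uint8),
        cat(p5s, int),
        cat(p3s, int),
    )


def damage_profile(
    fragments: Sequence[AlignedFragment], ref, window: int = 15
) -> DamageProfile:
    """Measure terminal C→T frequencies at read positions 1..window from
    each end, strand-aware (reference complemented for minus-strand
    fragments so everything is in read orientation)."""
    ref_codes = ref.encoded
    tmpl, base, pos5, pos3 = _stack_observations(fragments, ref_codes)
    is_c = tmpl == C
    is_ct = is_c & (base == T)

    def tally(pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        in_win = pos < window
        opp = np.bincount(pos[is_c & in_win], minlength=window)[:window]
        sub = np.bincount(pos[is_ct & in_win], minlength=window)[:window]
        return sub.astype(float), opp.astype(float)

    sub5, opp5 = tally(pos5)
    sub3, opp3 = tally(pos3)

    with np.errstate(invalid="ignore", divide="ignore"):
        ct5 = np.where(opp5 > 0, sub5 / np.maximum(opp5, 1), np.nan)
        ct3 = np.where(opp3 > 0, sub3 / np.maximum(opp3, 1), np.nan)

    def wilson(sub: np.ndarray, opp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.full(window, np.nan)
        hi = np.full(window, np.nan)
        has = opp > 0
        if has.any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                l, h = proportion_confint(sub[has], opp[has], method="wilson")
            lo[has], hi[has] = l, h
        return lo, hi

    ci5_low, ci5_high = wilson(sub5, opp5)
    ci3_low, ci3_high = wilson(sub3, opp3)
    return DamageProfile(
        window=window,
        ct5=ct5,
        ct3=ct3,
        sub5=sub5.astype(int),
        sub3=sub3.astype(int),
        opp5=opp5.astype(int),
        opp3=opp3.astype(int),
        ci5_low=ci5_low,
        ci5_high=ci5_high,
        ci3_low=ci3_low,
        ci3_high=ci3_high,
    )


def classify_deaminated(
    fragment: AlignedFragment, ref, terminal_window: int = 3
) -> bool:
    """True iff the fragment shows >=1 read-orientation C→T within
    ``terminal_window`` positions of either read end."""
    ref_codes = ref.encoded if hasattr(ref, "encoded") else ref
    tmpl, base, pos5, pos3 = _read_orientation_arrays(fragment, ref_codes)
    ct = (tmpl == C) & (base == T)
    return bool(np.any(ct & ((pos5 < terminal_window) | (pos3 < terminal_window))))


def deaminated_flags(
    fragments: Sequence[AlignedFragment], ref, terminal_window: int = 3
) -> np.ndarray:
    """Vector of :func:`classify_deaminated` over a fragment list."""
    ref_codes = ref.encoded
    return np.array(
        [classify_deaminated(f, ref_codes, terminal_window) for f in fragments],
        dtype=bool,
    )


def _per_fragment_damage_stats(
    fragments: Sequence[AlignedFragment], ref_codes: np.ndarray, window: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(5' opportunities, 5' substitutions, has-3'-damage) per fragment."""
    n = len(fragments)
    opp5 = np.zeros(n, dtype=np.int64)
    sub5 = np.zeros(n, dtype=np.int64)
    has3 = np.zeros(n, dtype=bool)
    for i, f in enumerate(fragments):
        tmpl, base, pos5, pos3 = _read_orientation_arrays(f, ref_codes)
        is_c = tmpl == C
        is_ct = is_c & (base == T)
        w5 = pos5 < window
        opp5[i] = int(np.sum(is_c & w5))
        sub5[i] = int(np.sum(is_ct & w5))
        has3[i] = bool(np.any(is_ct & (pos3 < window)))
    return opp5, sub5, has3


def estimate_contamination(
    fragments: Sequence[AlignedFragment],
    ref,
    error_rate: float,
    terminal_window: int = 3,
    n_boot: int = 200,
    seed: int = 0,
) -> ContaminationEstimate:
    """Conditional-damage mixture estimate of the present-day contaminant
    fraction (see module docstring for the model).

    The bootstrap resamples fragments; replicates where the conditional
    rate collapses below the error floor are discarded (counted via a
    warning if more than 10% are lost).
    """
    if len(fragments) < 500:
        warnings.warn(
            f"estimate_contamination: only {len(fragments)} fragments; "
            "the estimate will be noisy",
            stacklevel=2,
        )
    ref_codes = ref.encoded
    opp5, sub5, has3 = _per_fragment_damage_stats(fragments, ref_codes, terminal_window)
    eps = error_rate / 3.0

    def point_from(idx: np.ndarray) -> float:
        o, s, h = opp5[idx], sub5[idx], has3[idx]
        tot_opp = o.sum()
        cond_opp = o[h].sum()
        if tot_opp == 0 or cond_opp == 0:
            raise ContaminationUndefinedError("no terminal C opportunities")
        p_term = s.sum() / tot_opp
        p_cond = s[h].sum() / cond_opp
        if p_cond <= eps:
            raise ContaminationUndefinedError(
                f"conditional damage rate {p_cond:.4g} <= error floor {eps:.4g}; "
                "damage signal too weak to estimate contamination"
            )
        return float(np.clip(1.0 - (p_term - eps) / (p_cond - eps), 0.0, 1.0))

    all_idx = np.arange(len(fragments))
    point = point_from(all_idx)
    tot_opp = opp5.sum()
    cond_opp = opp5[has3].sum()
    p_terminal = float(sub5.sum() / tot_opp)
    p_conditional = float(sub5[has3].sum() / cond_opp)

    rng = np.random.default_rng(seed)
    boots = []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(fragments), size=len(fragments))
        try:
            boots.append(point_from(idx))
        except ContaminationUndefinedError:
            n_failed += 1
    if n_failed > 0.1 * n_boot:
        warnings.warn(
            f"estimate_contamination: {n_failed}/{n_boot} bootstrap replicates "
            "were undefined",
            stacklevel=2,
        )
    if boots:
        ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
        ci_low = float(min(ci_low, point))
        ci_high = float(max(ci_high, point))
    else:
        ci_low = ci_high = point
    return ContaminationEstimate(
        point=point,
        ci_low=ci_low,
        ci_high=ci_high,
        p_terminal=p_terminal,
        p_conditional=p_conditional,
        n_conditioning=int(has3.sum()),
        n_fragments=len(fragments),
        n_boot=n_boot,
        seed=seed,
    )
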