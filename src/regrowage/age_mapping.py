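"""Regenerating-forest age from an annual class time series.

A pixel is *designated* as regenerating forest in a target year when

* its class in the target year is REGROWTH,
* the terminal consecutive REGROWTH run has length >= ``min_regrowth_years``
  (default 3), and
* the most recent NONFOREST block before that run lasted
  >= ``min_nonforest_years`` consecutive years (default 3 — the annual-
  resolution proxy for "more than 2.5 years without tree cover").

The age of a designated pixel is the length of that terminal run, counting
the first REGROWTH year, so a 1990–2023 window yields ages in {0} ∪ [3, 34].
Any other class (DEGRADED, WATER, NODATA, ...) resets the run counter; a
configurable set of *neutral* classes can instead freeze it.

Left-censoring at the window start: a run (or its preceding NONFOREST block)
that touches the first year has its deforestation episode before the window,
so the gap requirement is waived — the source product's regrowth class
already encodes the prior deforestation event.  This is what makes the
maximum attainable age equal the window length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import logging

import numpy as np

from .stack_io import AgeMap, AnnualClassStack, ClassCode, MaskRaster

logger = logging.getLogger("regrowage")


@dataclass(frozen=True)
class AgeParams:
    """Parameters of the regrowth designation and age-counting rules."""

    min_regrowth_years: int = 3
    min_nonforest_years: int = 3
    first_year: int = 1990
    target_year: int = 2023
    #: classes that neither extend nor reset a regrowth run (none by default;
    #: add ClassCode.DEGRADED to treat degradation episodes as neutral)
    neutral_classes: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.min_regrowth_years < 1:
            raise ValueError("min_regrowth_years must be >= 1")
        if self.first_year >= self.target_year:
            raise ValueError("first_year must precede target_year")

    @property
    def max_age(self) -> int:
        return self.target_year - self.first_year + 1


def designate_regrowth(sequence: Sequence[int], params: AgeParams = AgeParams()) -> bool:
    """Scalar designation rule applied to one pixel's class sequence.

    ``sequence`` covers ``first_year..target_year`` inclusive.  Written as a
    direct scan of the sequence; the vectorised :func:`compute_age` must agree
    with run lengths derived from this rule.
    """
    n_expected = params.target_year - params.first_year + 1
    seq = [int(c) for c in sequence]
    if len(seq) != n_expected:
        raise ValueError(f"sequence length {len(seq)} != window length {n_expected}")
    return _terminal_age(seq, params) > 0


def _terminal_age(seq: list[int], params: AgeParams) -> int:
    """Age of the terminal regrowth run (0 if the pixel is not designated)."""
    R, N = int(ClassCode.REGROWTH), int(ClassCode.NONFOREST)
    neutral = {int(c) for c in params.neutral_classes}
    if seq[-1] != R:
        return 0
    # terminal run: scan back over REGROWTH (and neutral) years
    i = len(seq) - 1
    run = 0
    while i >= 0 and (seq[i] == R or seq[i] in neutral):
        if seq[i] == R:
            run += 1
        i -= 1
    if run < params.min_regrowth_years:
        return 0
    if i < 0:
        return run  # run touches window start: gap predates the window
    # most recent NONFOREST block before the run
    while i >= 0 and seq[i] != N:
        i -= 1
    gap = 0
    while i >= 0 and seq[i] == N:
        gap += 1
        i -= 1
    censored = i < 0 and gap > 0  # block touches window start
    if gap >= params.min_nonforest_years or censored:
        return run
    return 0


def compute_age(stack: AnnualClassStack, params: AgeParams = AgeParams()) -> AgeMap:
    """Vectorised per-pixel age for ``params.target_year``."""
    maps = _age_recursion(stack, params, keep_series=False)
    return maps[-1]


def compute_age_series(stack: AnnualClassStack, params: AgeParams = AgeParams()) -> list[AgeMap]:
    """One AgeMap per year from ``first_year`` to ``target_year`` (cumulative)."""
    return _age_recursion(stack, params, keep_series=True)


def _age_recursion(stack: AnnualClassStack, params: AgeParams, keep_series: bool) -> list[AgeMap]:
    y0, y1 = params.first_year, params.target_year
    if y0 < stack.years[0] or y1 > stack.years[-1]:
        raise ValueError(
            f"stack years {stack.years[0]}-{stack.years[-1]} do not cover "
            f"{y0}-{y1}")
    i0 = int(y0 - stack.years[0])
    i1 = int(y1 - stack.years[0])
    shape = stack.shape
    R, N = int(ClassCode.REGROWTH), int(ClassCode.NONFOREST)
    neutral_codes = np.array(sorted(int(c) for c in params.neutral_classes), dtype=np.uint8)

    run = np.zeros(shape, dtype=np.int16)          # terminal REGROWTH run length
    nf_run = np.zeros(shape, dtype=np.int16)       # current NONFOREST run
    last_nf = np.zeros(shape, dtype=np.int16)      # most recent NONFOREST block length
    last_nf_cens = np.zeros(shape, dtype=bool)     # that block touches window start
    gap_ok = np.zeros(shape, dtype=bool)           # gap condition of current run
    virgin = np.ones(shape, dtype=bool)            # only REGROWTH/neutral seen so far
    out: list[AgeMap] = []

    for t in range(i0, i1 + 1):
        cls = stack.grid[t]
        is_r = cls == R
        is_n = cls == N
        is_neutral = np.isin(cls, neutral_codes) if neutral_codes.size else np.zeros(shape, bool)

        # NONFOREST bookkeeping (a new block overwrites the previous one)
        block_start = is_n & (nf_run == 0)
        nf_run = np.where(is_n, nf_run + 1, 0).astype(np.int16)
        last_nf = np.where(is_n, nf_run, last_nf)
        last_nf_cens = np.where(block_start, t == i0, last_nf_cens)

        # regrowth run bookkeeping; a run whose backward scan (through
        # REGROWTH/neutral years) reaches the window start is left-censored
        run_start = is_r & (run == 0)
        gap_now = (last_nf >= params.min_nonforest_years) | last_nf_cens | virgin
        gap_ok = np.where(run_start, gap_now, gap_ok)
        run = np.where(is_r, run + 1,
                       np.where(is_neutral, run, 0)).astype(np.int16)
        virgin &= is_r | is_neutral

        if keep_series or t == i1:
            ages = np.where(is_r & (run >= params.min_regrowth_years) & gap_ok,
                            run, 0).astype(np.int16)
            year_params_target = int(stack.years[t])
            out.append(AgeMap(year_params_target, ages, stack.georef, stack.pixel_area))
    return out


def apply_mask(age_map: AgeMap, mask: MaskRaster) -> AgeMap:
    """Zero out masked pixels (e.g. mapped oil-palm plantations)."""
    if mask.data.shape != age_map.ages.shape:
        raise ValueError(
            f"mask shape {mask.data.shape} != age map shape {age_map.ages.shape}")
    if tuple(mask.georef.transform) != tuple(age_map.georef.transform):
        raise ValueError("mask georef does not match age map georef")
    n_masked = int((mask.data & (age_map.ages > 0)).sum())
    if n_masked:
        logger.info("apply_mask: %d regenerating pixels masked out", n_masked)
    ages = np.where(mask.data, 0, age_map.ages).astype(age_map.ages.dtype)
    return AgeMap(age_map.target_year, ages, age_map.georef, age_map.pixel_area)
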