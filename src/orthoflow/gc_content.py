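"""Base composition from paired AT-selective and intercalating dye runs.

An intercalating dye (propidium iodide) binds DNA irrespective of sequence, so
its sample/standard fluorescence ratio estimates the genome-size ratio alone.
An AT-selective dye (DAPI) needs a run of ``n`` consecutive AT base pairs per
binding site, making its signal proportional to genome size times
(AT fraction)^n.  Measuring the same specimen with both dyes against a
standard of known base composition therefore determines the sample's AT
fraction:

    r_AT / r_int = (p_sample / p_standard)^n
    p_sample     = p_standard * (r_AT / r_int)^(1/n)

with p the genomic AT fraction and r the sample/standard ratios.  GC content
is 100*(1 - p_sample).  The binding length defaults to n = 4, the
conventional value for DAPI, and is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidFractionError, InvalidRatioError
from .histograms import GC_OUT_OF_RANGE, RELATIVE, Dye, StandardRef

_EPS = 1e-12


@dataclass(frozen=True)
class DyePair:
    """Paired same-specimen ratios under the two dye classes."""

    ratio_at_dye: float
    ratio_intercalating: float
    standard: StandardRef
    binding_length: int = 4

    def __post_init__(self):
        if self.ratio_at_dye <= 0 or self.ratio_intercalating <= 0:
            raise InvalidRatioError("invalid-ratios: ratios must be positive")
        if self.binding_length < 1:
            raise InvalidRatioError("invalid-ratios: binding_length must be >= 1")


def forward_dye_ratio(p_sample: float, p_standard: float,
                      binding_length: int) -> float:
    """Expected r_AT/r_int for given sample and standard AT fractions.

    Strictly increasing in ``p_sample``; used by the simulator and as the
    inversion oracle in tests.
    """
    if not (0 < p_sample < 1 and 0 < p_standard < 1):
        raise InvalidFractionError("invalid-fraction: AT fractions must be in (0, 1)")
    if binding_length < 1:
        raise InvalidFractionError("invalid-fraction: binding_length must be >= 1")
    return (p_sample / p_standard) ** binding_length


def at_proportion_raw(d: DyePair) -> float:
    """Unclipped AT fraction estimate; may leave (0,1) under noisy ratios."""
    q = d.ratio_at_dye / d.ratio_intercalating
    if q <= 0:
        raise InvalidRatioError("invalid-ratios: non-positive ratio quotient")
    return d.standard.at_fraction * q ** (1.0 / d.binding_length)


def at_proportion(d: DyePair) -> float:
    """AT fraction of the sample genome, clipped into (0, 1).

    Noisy ratios can push the raw estimate out of range; use
    :func:`is_out_of_range` (or the table-level API, which sets a
    ``GC_OUT_OF_RANGE`` flag) to detect that.
    """
    return float(np.clip(at_proportion_raw(d), _EPS, 1.0 - _EPS))


def is_out_of_range(d: DyePair) -> bool:
    p = at_proportion_raw(d)
    return not 0.0 < p < 1.0


def gc_percent(d: DyePair) -> float:
    """Percent GC of the sample genome."""
    return 100.0 * (1.0 - at_proportion(d))


def add_gc_to_measurements(measurements: pd.DataFrame, standard: StandardRef,
                           binding_length: int = 4) -> pd.DataFrame:
    """Pair per-specimen dye rows and append GC estimates.

    Expects the measurement table contract (columns ``specimen_id``, ``dye``,
    ``ratio``, ``qc_flags``).  Specimens measured with the AT-selective dye
    only yield a *relative* genome size (the AT-dye signal depends on base
    composition too); they get a RELATIVE flag and no GC value.  Raw AT
    fractions outside (0,1) are clipped and flagged GC_OUT_OF_RANGE.
    """
    df = measurements.copy()
    df["gc_percent"] = np.nan
    flags = df["qc_flags"].fillna("").astype(str).tolist() \
        if "qc_flags" in df else [""] * len(df)

    for specimen, grp in df.groupby("specimen_id"):
        by_dye = {Dye.parse(d): i for i, d in zip(grp.index, grp["dye"])}
        has_at = Dye.AT_SELECTIVE in by_dye
        has_int = Dye.INTERCALATING in by_dye
        if has_at and has_int:
            pair = DyePair(float(df.loc[by_dye[Dye.AT_SELECTIVE], "ratio"]),
                           float(df.loc[by_dye[Dye.INTERCALATING], "ratio"]),
                           standard, binding_length)
            gc = gc_percent(pair)
            for i in by_dye.values():
                df.loc[i, "gc_percent"] = gc
                if is_out_of_range(pair):
                    pos = df.index.get_loc(i)
                    flags[pos] = _add_flag(flags[pos], GC_OUT_OF_RANGE)
        elif has_at and not has_int:
            pos = df.index.get_loc(by_dye[Dye.AT_SELECTIVE])
            flags[pos] = _add_flag(flags[pos], RELATIVE)
    df["qc_flags"] = flags
    return df


def _add_flag(existing: str, flag: str) -> str:
    parts = [p for p in existing.split(";") if p]
    if flag not in parts:
        parts.append(flag)
    return ";".join(sorted(parts))
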