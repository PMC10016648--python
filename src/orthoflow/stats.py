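"""Species-level aggregation and comparative statistics.

Covers the analyses typically run on a genome-size survey: per-species
per-sex means, female-minus-male differences (which under XX/X0 sex
determination estimate the X chromosome's DNA content), Kruskal-Wallis and
pairwise Bonferroni-corrected Mann-Whitney tests of genome size across
chromosome-number groups, Pearson correlation, and one-way ANOVA plus
pairwise contrasts of GC content across families.

Test statistics come from scipy.stats; this module owns grouping, filtering
rules, the Bonferroni family size (the number of pairs actually tested) and
the output table contracts.
"""

from __future__ import annotations

import enum
import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, InsufficientGroupsError
from .histograms import Measurement, Sex, measurements_to_frame

logger = logging.getLogger(__name__)


class Provenance(str, enum.Enum):
    SAME_STUDY = "SAME_STUDY"
    CROSS_STUDY = "CROSS_STUDY"      # sexes measured in different studies, same method
    CROSS_METHOD = "CROSS_METHOD"    # e.g. flow cytometry vs Feulgen densitometry


class SexSystem(str, enum.Enum):
    XX_X0 = "XX_X0"
    XX_XY = "XX_XY"
    UNKNOWN = "UNKNOWN"


@dataclass
class SpeciesSummary:
    species: str
    family: str = ""
    subfamily: str = ""
    n_female: int = 0
    n_male: int = 0
    mean_1C_female_pg: float | None = None
    mean_1C_male_pg: float | None = None
    mean_gc_percent: float | None = None
    male_2n: int | None = None
    sex_system: SexSystem = SexSystem.UNKNOWN


@dataclass
class SexDifference:
    """Female minus male mean 1C; under XX/X0 an estimate of the X size."""

    species: str
    delta_pg: float
    provenance: Provenance = Provenance.SAME_STUDY


@dataclass
class GroupTestResult:
    statistic: float
    df: float | None
    p_value: float
    groups: tuple
    corrected: bool = False


def _as_measurement_frame(measurements) -> pd.DataFrame:
    if isinstance(measurements, pd.DataFrame):
        return measurements
    meas = list(measurements)
    if meas and isinstance(meas[0], Measurement):
        return measurements_to_frame(meas)
    return pd.DataFrame(meas)


def aggregate_species(measurements, taxonomy: Mapping[str, tuple] | None = None,
                      karyotype: Mapping[str, int] | None = None,
                      ) -> list[SpeciesSummary]:
    """Aggregate specimen measurements to per-species per-sex means.

    Each specimen contributes once (its dye replicates are averaged first),
    then 1C means are taken per sex and GC over all specimens of the species.
    Species with zero usable measurements are omitted with a log entry.
    """
    df = _as_measurement_frame(measurements)
    if df.empty:
        return []
    taxonomy = taxonomy or {}
    karyotype = karyotype or {}

    per_specimen = (df.groupby(["species", "specimen_id", "sex"], dropna=False)
                      .agg(c1_pg=("c1_pg", "mean"),
                           gc_percent=("gc_percent", "mean")
                           if "gc_percent" in df.columns else ("c1_pg", "size"))
                      .reset_index())
    if "gc_percent" not in df.columns:
        per_specimen["gc_percent"] = np.nan

    out = []
    for species, grp in per_specimen.groupby("species", sort=True):
        if grp["c1_pg"].isna().all():
            logger.info("species %s omitted: no usable measurements", species)
            continue
        fem = grp[grp["sex"] == Sex.F.value]["c1_pg"].dropna()
        mal = grp[grp["sex"] == Sex.M.value]["c1_pg"].dropna()
        gc = grp["gc_percent"].dropna()
        fam, sub = taxonomy.get(species, ("", ""))
        out.append(SpeciesSummary(
            species=species, family=fam, subfamily=sub,
            n_female=int(fem.size), n_male=int(mal.size),
            mean_1C_female_pg=float(fem.mean()) if fem.size else None,
            mean_1C_male_pg=float(mal.mean()) if mal.size else None,
            mean_gc_percent=float(gc.mean()) if gc.size else None,
            male_2n=karyotype.get(species)))
    return out


def summaries_to_frame(summaries: Iterable[SpeciesSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "species": s.species, "family": s.family, "subfamily": s.subfamily,
        "n_female": s.n_female, "n_male": s.n_male,
        "mean_1C_female_pg": s.mean_1C_female_pg,
        "mean_1C_male_pg": s.mean_1C_male_pg,
        "mean_gc_percent": s.mean_gc_percent, "male_2n": s.male_2n,
        "sex_system": s.sex_system.value if isinstance(s.sex_system, SexSystem)
        else s.sex_system} for s in summaries])


def sex_differences(summaries: Iterable[SpeciesSummary],
                    provenance: Mapping[str, Provenance] | None = None,
                    ) -> list[SexDifference]:
    """Female-minus-male 1C per species, for species with both sex means."""
    provenance = provenance or {}
    out = []
    for s in summaries:
        if s.mean_1C_female_pg is None or s.mean_1C_male_pg is None:
            continue
        out.append(SexDifference(
            species=s.species,
            delta_pg=s.mean_1C_female_pg - s.mean_1C_male_pg,
            provenance=Provenance(provenance.get(s.species,
                                                 Provenance.SAME_STUDY))))
    return out


def _split_groups(values: Iterable[tuple]) -> dict:
    groups: dict = {}
    for key, v in values:
        groups.setdefault(key, []).append(float(v))
    return groups


def kruskal_wallis(values: Iterable[tuple]) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p on k-1 df.

    ``values`` is an iterable of (group_key, value) pairs.
    """
    groups = _split_groups(values)
    if len(groups) < 2:
        raise InsufficientGroupsError("insufficient-groups: need >= 2 groups")
    keys = sorted(groups)
    samples = [groups[k] for k in keys]
    if np.ptp(np.concatenate(samples)) == 0:
        # all values identical: H = 0, p = 1 by convention
        return GroupTestResult(0.0, len(keys) - 1, 1.0, tuple(keys))
    stat, p = sps.kruskal(*samples)
    return GroupTestResult(float(stat), len(keys) - 1, float(p), tuple(keys))


def mann_whitney_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney p.

    Exact U distribution when both groups have <= 8 values and the pooled
    data are tie-free; tie-corrected normal approximation (no continuity
    correction) otherwise.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if len(x) <= 8 and len(y) <= 8 and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=False)
    return float(res.pvalue)


def pairwise_mann_whitney_bonferroni(values: Iterable[tuple],
                                     min_group_size: int = 2) -> pd.DataFrame:
    """All-pairs Mann-Whitney with Bonferroni correction.

    Groups with fewer than ``min_group_size`` values are excluded before
    pairing; the Bonferroni family size is the number of pairs actually
    tested.  Returns a symmetric DataFrame of corrected p-values (diagonal
    NaN), indexed by the sorted eligible group keys.
    """
    groups = {k: v for k, v in _split_groups(values).items()
              if len(v) >= min_group_size}
    keys = sorted(groups)
    pairs = list(itertools.combinations(keys, 2))
    if not pairs:
        raise InsufficientGroupsError(
            "insufficient-groups: fewer than 2 groups pass min_group_size")
    m = len(pairs)
    mat = pd.DataFrame(np.nan, index=keys, columns=keys)
    for a, b in pairs:
        p = min(1.0, mann_whitney_p(groups[a], groups[b]) * m)
        mat.loc[a, b] = mat.loc[b, a] = p
    return mat


def pearson_test(x: Sequence[float], y: Sequence[float]) -> GroupTestResult:
    """Pearson correlation with two-sided t-based p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise DegenerateInputError("degenerate-input: need equal lengths >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("degenerate-input: zero variance")
    r, p = sps.pearsonr(x, y)
    return GroupTestResult(float(r), float(x.size - 2), float(p), ("x", "y"))


def t_test(x: Sequence[float], y: Sequence[float]) -> GroupTestResult:
    """Two-sample two-sided t-test (equal-variance), e.g. GC by sex."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise DegenerateInputError("degenerate-input: need >= 2 per group")
    t, p = sps.ttest_ind(x, y)
    return GroupTestResult(float(t), float(x.size + y.size - 2), float(p),
                           ("x", "y"))


@dataclass
class FamilyGCContrasts:
    """One-way ANOVA + pairwise contrasts + summary of GC across families."""

    anova: GroupTestResult
    pairwise: pd.DataFrame
    summary: pd.DataFrame = field(repr=False)


def gc_family_contrasts(per_specimen_gc: Iterable[tuple],
                        min_group_size: int = 2) -> FamilyGCContrasts:
    """Family-level GC comparison.

    ``per_specimen_gc`` is an iterable of (family, sex, gc_percent) triples.
    Returns the ANOVA F test across families, the Bonferroni-corrected
    pairwise Mann-Whitney matrix, and a per-family table with N, max, min,
    mean and sd (ddof=1).
    """
    records = [(fam, float(gc)) for fam, _sex, gc in per_specimen_gc
               if gc is not None and np.isfinite(gc)]
    groups = _split_groups(records)
    if len(groups) < 2:
        raise InsufficientGroupsError("insufficient-groups: need >= 2 families")
    keys = sorted(groups)
    f, p = sps.f_oneway(*[groups[k] for k in keys])
    anova = GroupTestResult(float(f), float(len(keys) - 1), float(p),
                            tuple(keys))
    pairwise = pairwise_mann_whitney_bonferroni(records, min_group_size)
    rows = []
    for k in keys:
        v = np.asarray(groups[k])
        rows.append({"family": k, "n": v.size, "max": v.max(), "min": v.min(),
                     "mean": v.mean(),
                     "sd": v.std(ddof=1) if v.size > 1 else np.nan})
    return FamilyGCContrasts(anova, pairwise, pd.DataFrame(rows))
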