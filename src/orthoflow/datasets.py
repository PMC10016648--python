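"""Bundled reference tables of published species-level measurements.

``measured_species.csv`` holds the species-level results of a 50-species
flow-cytometric survey of orthopteran genome sizes (per-sex 1C means in pg,
mean GC percent, male diploid chromosome number and sex-chromosome system);
``sex_difference_pairs.csv`` holds compiled female/male 1C means for species
whose sex difference — the X chromosome size under XX/X0 — was worked out
across studies.  Both are species-level summaries: the underlying raw
fluorescence histograms were never published, so histogram-level behaviour is
exercised with the synthetic generators instead.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .stats import Provenance, SexSystem, SpeciesSummary


def _read(name: str) -> pd.DataFrame:
    with resources.files("orthoflow.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_measured_species() -> pd.DataFrame:
    """Species-level survey results (one row per species).

    Columns: species, family, n_female, n_male, c1_female_pg, c1_male_pg,
    gc_percent, male_2n, sex_system, karyotype_from_congener.
    """
    return _read("measured_species.csv")


def load_sex_difference_pairs() -> pd.DataFrame:
    """Compiled female/male 1C means for sex-difference worked examples."""
    return _read("sex_difference_pairs.csv")


def measured_species_summaries() -> list[SpeciesSummary]:
    """The survey table as :class:`~orthoflow.stats.SpeciesSummary` objects."""
    out = []
    for _, r in load_measured_species().iterrows():
        out.append(SpeciesSummary(
            species=r["species"], family=r["family"],
            n_female=int(r["n_female"]), n_male=int(r["n_male"]),
            mean_1C_female_pg=None if pd.isna(r["c1_female_pg"])
            else float(r["c1_female_pg"]),
            mean_1C_male_pg=None if pd.isna(r["c1_male_pg"])
            else float(r["c1_male_pg"]),
            mean_gc_percent=float(r["gc_percent"]),
            male_2n=int(r["male_2n"]),
            sex_system=SexSystem(r["sex_system"])))
    return out


def sex_pair_summaries() -> tuple[list[SpeciesSummary], dict]:
    """Sex-difference pairs as summaries plus their provenance map."""
    out, prov = [], {}
    for _, r in load_sex_difference_pairs().iterrows():
        out.append(SpeciesSummary(
            species=r["species"], family=r["family"], n_female=1, n_male=1,
            mean_1C_female_pg=float(r["c1_female_pg"]),
            mean_1C_male_pg=float(r["c1_male_pg"]),
            sex_system=SexSystem.XX_X0))
        prov[r["species"]] = Provenance(r["provenance"])
    return out, prov
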