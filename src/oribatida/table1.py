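"""Packaged transcription of the study's regional species table.

The table lists, for each taxon and region (Swabian Alb ``ALB``,
Schorfheide-Chorin ``SCH``): total adult individuals, the percentage of those
individuals collected in forests vs. grasslands ("% occurrence"; the two
percentages complement to 100 within a row), the percentage of females and
the mean egg count per gravid female in each habitat, and the reproductive
mode (sexual / parthenogenetic).

Row types
---------
``species``
    One row per taxon and region. Morphospecies identified only to genus or
    family ("spp.", family-level rows) count as distinct taxa.
``higher_taxon``
    Printed suborder-level summaries (Enarthronota, Phthiracaroidea,
    Desmonomata, Circumdehiscentiae). Excluded from species-level
    computations; within each region their totals sum exactly to the
    regional total, which the individual species rows do not quite do (the
    source table is internally inconsistent at the species level).
``mode_total``
    Printed per-mode summaries. Beware the changed column semantics: here
    ``occ_forest``/``occ_grassland`` hold the mode's share of that habitat's
    individuals (sexual + parthenogenetic = 100 within a habitat), not the
    habitat split of the mode's individuals.
``region_total``
    The printed regional grand totals (17,611 ALB; 14,931 SCH). In ALB the
    printed mode totals sum to 17,511 — a known inconsistency of the source;
    consistency checks therefore use SCH.

Cells printed as a dash parse to missing (NaN), never zero: a dash means
"not observed / not applicable" and computations skip such cells.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

_FIXTURE_NAME = "table1_oribatida.csv"
#: sha256 of the packaged fixture; guards against silent corruption
_FIXTURE_SHA256 = "b7871a0ae47ffc52f71048f377172d89a64e8af20cc62822cf76b480315c1cd5"

NUMERIC_COLS = [
    "total",
    "occ_forest",
    "fem_forest",
    "eggs_forest",
    "occ_grassland",
    "fem_grassland",
    "eggs_grassland",
]


class IntegrityError(RuntimeError):
    """The packaged fixture does not match its recorded checksum."""


@dataclass
class Table1:
    """The species table as a tidy DataFrame plus typed accessors."""

    data: pd.DataFrame

    def species_rows(self, region: str | None = None) -> pd.DataFrame:
        df = self.data[self.data.row_type == "species"]
        return df if region is None else df[df.region == region]

    def higher_taxon_rows(self, region: str | None = None) -> pd.DataFrame:
        df = self.data[self.data.row_type == "higher_taxon"]
        return df if region is None else df[df.region == region]

    def mode_totals(self, region: str) -> pd.Series:
        """Printed per-mode individual totals for one region."""
        df = self.data[(self.data.row_type == "mode_total") & (self.data.region == region)]
        return df.set_index("mode")["total"]

    def mode_total_rows(self, region: str | None = None) -> pd.DataFrame:
        df = self.data[self.data.row_type == "mode_total"]
        return df if region is None else df[df.region == region]

    def region_total(self, region: str) -> int:
        df = self.data[(self.data.row_type == "region_total") & (self.data.region == region)]
        return int(df["total"].iloc[0])

    def habitat_abundance(self, region: str, rows: str = "species") -> pd.DataFrame:
        """Estimated individuals per habitat: total x %occurrence / 100.

        ``rows`` selects ``"species"`` or ``"higher_taxon"`` source rows;
        taxa whose occurrence split was not printed are dropped.
        """
        if rows not in ("species", "higher_taxon"):
            raise ValueError("rows must be 'species' or 'higher_taxon'")
        df = self.data[(self.data.row_type == rows) & (self.data.region == region)]
        df = df.dropna(subset=["occ_forest", "occ_grassland"])
        out = df[["taxon", "mode", "total"]].copy()
        out["forest"] = df["total"] * df["occ_forest"] / 100.0
        out["grassland"] = df["total"] * df["occ_grassland"] / 100.0
        return out.reset_index(drop=True)


def load_table1(verify_checksum: bool = True) -> Table1:
    """Load the packaged species table, verifying its checksum by default."""
    ref = resources.files("oribatida").joinpath("data", _FIXTURE_NAME)
    raw = ref.read_bytes()
    if verify_checksum:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _FIXTURE_SHA256:
            raise IntegrityError(
                f"packaged {_FIXTURE_NAME} has sha256 {digest}, "
                f"expected {_FIXTURE_SHA256}"
            )
    with ref.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    for col in NUMERIC_COLS:
        df[col] = pd.to_numeric(df[col])
    return Table1(df)
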