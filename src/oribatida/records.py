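"""Core record types for the sampling design and specimen data.

The study design is a factorial plot network: two regions (Swabian Alb,
``ALB``; Schorfheide-Chorin, ``SCH``), two habitat types (forest, grassland),
fifteen plots per region x habitat, five quadrat subsamples per plot. Each
plot carries the land-use intensity parameters of its habitat: forests a
forest-management index (Formi) with components Iharv (proportion of
harvested trees), Inonat (proportion of non-native trees) and Idwcut
(proportion of dead wood with saw cuts), all proportions in [0, 1];
grasslands a compound land-use index (LUI) with components fertilization
(kg N ha-1 yr-1), mowing (cuts yr-1) and grazing (livestock-unit days
ha-1 yr-1), all non-negative rates.

Specimens are individually sexed adult mites; for females, gravidity and the
number of eggs carried were recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

REGIONS = ("ALB", "SCH")
HABITATS = ("forest", "grassland")
SEXES = ("female", "male", "undetermined")
MODES = ("sexual", "parthenogenetic", "unknown")
MODE_SOURCES = ("sex_ratio_rule", "literature")

#: land-use parameters constrained to [0, 1]
PROPORTION_PARAMS = frozenset({"Iharv", "Inonat", "Idwcut"})
#: land-use parameters constrained to be non-negative rates
RATE_PARAMS = frozenset({"fertilization", "mowing", "grazing", "LUI"})

FOREST_PARAMS = frozenset({"Formi", "Iharv", "Inonat", "Idwcut"})
GRASSLAND_PARAMS = frozenset({"LUI", "fertilization", "mowing", "grazing"})

#: conventional quadrat side length (cm) per habitat
SAMPLE_SIDE_CM = {"forest": 15.0, "grassland": 20.0}


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class FormatError(ValueError):
    """An input table does not have the expected layout."""


@dataclass(frozen=True)
class PlotRecord:
    """One study plot with its land-use parameter values.

    ``landuse`` maps parameter names to values; unknown parameter names are
    preserved untouched, known ones are bounds-checked. Region and habitat
    are authoritative here — they are never parsed out of plot identifiers.
    """

    plot_id: str
    region: str
    habitat: str
    landuse: dict[str, float] = field(default_factory=dict)
    sample_side_cm: float = 0.0
    n_subsamples: int = 5

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValidationError(
                f"plot {self.plot_id!r}: region must be one of {REGIONS}, got {self.region!r}"
            )
        if self.habitat not in HABITATS:
            raise ValidationError(
                f"plot {self.plot_id!r}: habitat must be one of {HABITATS}, got {self.habitat!r}"
            )
        if self.sample_side_cm == 0.0:
            object.__setattr__(self, "sample_side_cm", SAMPLE_SIDE_CM[self.habitat])
        if self.sample_side_cm <= 0:
            raise ValidationError(f"plot {self.plot_id!r}: sample_side_cm must be > 0")
        if self.n_subsamples <= 0:
            raise ValidationError(f"plot {self.plot_id!r}: n_subsamples must be > 0")
        wrong = (GRASSLAND_PARAMS if self.habitat == "forest" else FOREST_PARAMS)
        clash = wrong.intersection(self.landuse)
        if clash:
            raise ValidationError(
                f"plot {self.plot_id!r}: {sorted(clash)} do not apply to {self.habitat} plots"
            )
        for name, value in self.landuse.items():
            if value != value:  # NaN
                raise ValidationError(f"plot {self.plot_id!r}: {name} is NaN")
            if name in PROPORTION_PARAMS and not 0.0 <= value <= 1.0:
                raise ValidationError(
                    f"plot {self.plot_id!r}: {name}={value} outside [0, 1]"
                )
            if name in RATE_PARAMS and value < 0:
                raise ValidationError(f"plot {self.plot_id!r}: {name}={value} < 0")

    @property
    def sampled_area_m2(self) -> float:
        """Total area sampled on the plot (all subsamples pooled), in m^2."""
        return self.n_subsamples * (self.sample_side_cm / 100.0) ** 2


@dataclass(frozen=True)
class SpecimenRecord:
    """One identified adult mite.

    Gravidity is meaningful only for females; a gravid female carries at
    least one egg and non-gravid individuals carry none.
    """

    plot_id: str
    subsample_id: int
    species: str
    sex: str
    gravid: bool = False
    egg_count: int = 0

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValidationError(
                f"specimen of {self.species!r}: sex must be one of {SEXES}, got {self.sex!r}"
            )
        if self.egg_count < 0:
            raise ValidationError(f"specimen of {self.species!r}: egg_count < 0")
        if self.gravid:
            if self.sex != "female":
                raise ValidationError(
                    f"specimen of {self.species!r}: gravid specimen must be female"
                )
            if self.egg_count < 1:
                raise ValidationError(
                    f"specimen of {self.species!r}: gravid female must carry >= 1 egg"
                )
        elif self.egg_count != 0:
            raise ValidationError(
                f"specimen of {self.species!r}: non-gravid specimen with egg_count > 0"
            )


#: plausibility band for adult oribatid body length (um); values outside warn
BODY_SIZE_BAND_UM = (100.0, 1000.0)


@dataclass(frozen=True)
class SpeciesTrait:
    """Per-species traits: reproductive mode and mean adult body length."""

    species: str
    mode: str = "unknown"
    mode_source: str = "sex_ratio_rule"
    body_size_um: float | None = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValidationError(
                f"{self.species!r}: mode must be one of {MODES}, got {self.mode!r}"
            )
        if self.mode_source not in MODE_SOURCES:
            raise ValidationError(
                f"{self.species!r}: mode_source must be one of {MODE_SOURCES}"
            )
        if self.body_size_um is not None:
            if self.body_size_um <= 0:
                raise ValidationError(f"{self.species!r}: body_size_um must be > 0")
            lo, hi = BODY_SIZE_BAND_UM
            if not lo <= self.body_size_um <= hi:
                warnings.warn(
                    f"{self.species}: body size {self.body_size_um} um outside the "
                    f"plausibility band [{lo}, {hi}] for adult oribatid mites",
                    stacklevel=2,
                )
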