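"""Mutation-density estimation and screen-design statistics for TILLING.

A TILLING assay screens a ~1 kb amplicon across N pooled M2 plants and
counts the point mutations detected.  From (amplicon length x plants
screened / mutations detected) one obtains the screened-bp-per-mutation
density, conventionally rendered "1/X kb".  Because EMS hits only G/C
sites, densities measured on amplicons of different GC content are made
comparable by rescaling to a reference GC level; extrapolating the
genome-wide per-plant mutation load then only needs a genome size.

The module also provides the screen-design formulas: the probability that
a screen yielding E expected mutations contains at least one stop-codon
(nonsense) hit, the fraction of the genome's G/C sites mutated somewhere
in the whole population (saturation), the exon mutation budget of a
single plant, and the residual load after backcross generations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .genetic_code import MISSENSE, NONSENSE, SILENT, SpectrumSummary

#: Nonsense fraction of EMS coding hits under uniform codon usage (5 of
#: the 96 mutable positions of the genetic code create a stop codon).
NONSENSE_FRACTION = 5.0 / 96.0


class DensityUndefinedError(ZeroDivisionError):
    """Raised when a density is requested for an assay with zero mutations."""


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (display convention).

    Spreadsheet-style rounding; Python's banker's rounding would send
    e.g. 10105.5 to 10105 and fail to reproduce conventional tables.
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ScreenAssay:
    """Raw result of one TILLING assay (one amplicon, one population)."""

    gene_name: str
    ems_dose: float  # EMS concentration used for the population, percent
    amplicon_length: int  # bp
    gc_percent: float  # amplicon GC, percent
    mutations_detected: int
    plants_screened: int
    population_size: int

    def __post_init__(self) -> None:
        if self.mutations_detected < 0:
            raise ValueError("mutations_detected must be >= 0")
        if self.plants_screened < 1:
            raise ValueError("plants_screened must be >= 1")
        if not 0 < self.gc_percent < 100:
            raise ValueError("gc_percent must be in (0, 100)")
        if self.plants_screened > self.population_size:
            raise ValueError("plants_screened exceeds population_size")


@dataclass(frozen=True)
class PopulationConstants:
    """Genome-level constants used for extrapolation.

    Defaults describe the Brassica rapa TILLING platform: a ~500 Mbp
    genome at 35% GC of which ~11% is coding sequence averaging 41% GC.
    """

    genome_size: float = 5.0e8  # bp
    genome_gc: float = 35.0  # percent
    exon_fraction: float = 0.11
    exon_gc: float = 41.0  # percent

    def __post_init__(self) -> None:
        if min(self.genome_size, self.genome_gc, self.exon_fraction, self.exon_gc) <= 0:
            raise ValueError("all population constants must be positive")
        if not 0 < self.exon_fraction < 1:
            raise ValueError("exon_fraction must be in (0, 1)")


@dataclass(frozen=True)
class DensityEstimate:
    """Raw and GC-normalized density plus per-plant load for one assay."""

    bp_per_mutation_raw: float
    bp_per_mutation_norm: float
    mutations_per_plant_raw: int
    mutations_per_plant_norm: int
    reference_gc: float


@dataclass(frozen=True)
class ClassCompositionReport:
    """Observed vs expected mutation-class composition of a screen."""

    observed: dict[str, int]
    expected: dict[str, float]
    total: int = field(default=0)


def bp_per_mutation(assay: ScreenAssay) -> float:
    """Screened base pairs per detected mutation (unrounded).

    Raises :class:`DensityUndefinedError` when no mutations were detected
    (the density is undefined, not infinite).
    """
    if assay.mutations_detected == 0:
        raise DensityUndefinedError(
            f"{assay.gene_name}: no mutations detected, density undefined"
        )
    return assay.amplicon_length * assay.plants_screened / assay.mutations_detected


def format_density(bp: float) -> str:
    """Render a bp-per-mutation value in the conventional '1/X kb' form."""
    return f"1/{round_half_up(bp / 1000.0)}"


def normalize_bp_per_mutation(bp: float, gc_from: float, gc_to: float) -> float:
    """Rescale a density measured at ``gc_from``% GC to ``gc_to``% GC.

    EMS mutates only G/C sites, so the per-bp mutation rate is
    proportional to GC content and bp-per-mutation scales inversely:
    ``bp * gc_from / gc_to``.
    """
    if gc_from <= 0 or gc_to <= 0 or gc_from >= 100 or gc_to >= 100:
        raise ValueError("GC percentages must be in (0, 100)")
    return bp * gc_from / gc_to


def mutations_per_plant(
    bp_per_mut: float, constants: PopulationConstants = PopulationConstants()
) -> int:
    """Genome-wide mutation load of one plant, rounded to an integer."""
    if bp_per_mut <= 0:
        raise ValueError("bp_per_mut must be positive")
    return round_half_up(constants.genome_size / bp_per_mut)


def expected_mutations(n_plants: int, length: float, bp_per_mut: float) -> float:
    """Expected mutation count when screening ``length`` bp in ``n_plants``."""
    if n_plants < 0 or length <= 0 or bp_per_mut <= 0:
        raise ValueError("arguments must be positive (n_plants may be 0)")
    return n_plants * length / bp_per_mut


def density_estimate(
    assay: ScreenAssay, constants: PopulationConstants = PopulationConstants()
) -> DensityEstimate:
    """Full density/load estimate for one assay, normalized to genome GC.

    The displayed normalized load is derived from the rounded raw load
    (the convention used in published TILLING density tables).
    """
    raw = bp_per_mutation(assay)
    norm = normalize_bp_per_mutation(raw, assay.gc_percent, constants.genome_gc)
    load_raw = mutations_per_plant(raw, constants)
    load_norm = round_half_up(load_raw * constants.genome_gc / assay.gc_percent)
    return DensityEstimate(
        bp_per_mutation_raw=raw,
        bp_per_mutation_norm=norm,
        mutations_per_plant_raw=load_raw,
        mutations_per_plant_norm=load_norm,
        reference_gc=constants.genome_gc,
    )


def p_at_least_one_nonsense(
    expected_mut: float, nonsense_fraction: float = NONSENSE_FRACTION
) -> float:
    """Probability that a screen yields at least one stop-codon mutation.

    With E mutations expected and each an independent nonsense hit with
    probability f, P = 1 - (1 - f)^E.  E.g. a standard 3,072-plant screen
    of a 1 kb exonic amplicon yields ~68 mutations and P ~ 0.97.
    """
    if expected_mut < 0:
        raise ValueError("expected_mut must be >= 0")
    if not 0 <= nonsense_fraction <= 1:
        raise ValueError("nonsense_fraction must be in [0, 1]")
    return 1.0 - (1.0 - nonsense_fraction) ** expected_mut


def saturation_fraction(
    per_plant_loads: list[tuple[float, int]],
    constants: PopulationConstants = PopulationConstants(),
    collision_corrected: bool = False,
) -> float:
    """Fraction of the genome's G/C sites mutated somewhere in the population.

    ``per_plant_loads`` pairs a (GC-normalized) per-plant mutation load
    with the number of plants carrying it.  The naive mode divides the
    total mutation count by the number of G/C sites; the collision-
    corrected mode treats hits as Poisson over sites and returns
    ``1 - exp(-lambda)``, which accounts for two plants hitting the same
    site and is therefore always the smaller number.
    """
    total = sum(load * n for load, n in per_plant_loads)
    if total < 0:
        raise ValueError("loads and plant counts must be non-negative")
    gc_sites = constants.genome_size * constants.genome_gc / 100.0
    lam = total / gc_sites
    if collision_corrected:
        return 1.0 - math.exp(-lam)
    return lam


def exon_budget(
    per_plant_load: float,
    constants: PopulationConstants = PopulationConstants(),
    spectrum: SpectrumSummary | None = None,
) -> tuple[float, float, float]:
    """Split a per-plant mutation load into exonic / aa-changing / nonsense.

    Only ``exon_fraction`` of the genome is coding, and of coding hits
    the genetic code lets (mis-sense + nonsense)/96 change the protein
    and 5/96 truncate it.  Returns unrounded expected counts.
    """
    if per_plant_load < 0:
        raise ValueError("per_plant_load must be >= 0")
    if spectrum is None:
        from .genetic_code import code_spectrum

        spectrum = code_spectrum()
    exonic = per_plant_load * constants.exon_fraction
    m = spectrum.mutable_positions
    aa_changing = exonic * (spectrum.mis_sense + spectrum.nonsense) / m
    nonsense = exonic * spectrum.nonsense / m
    return exonic, aa_changing, nonsense


def backcross_load(initial_load: float, generations: int) -> float:
    """Mutation load left after repeated backcrossing to wild type.

    Each backcross generation halves the load: load x 0.5**generations.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    return initial_load * 0.5**generations


def summarize_assays(
    assays: list[ScreenAssay],
    constants: PopulationConstants = PopulationConstants(),
    yield_length: float = 1000.0,
) -> pd.DataFrame:
    """Derived density table for a list of assays, with per-dose averages.

    For each assay the table reports the density (raw and normalized to
    genome GC, as '1/X kb' integers), the per-plant load (raw and
    normalized) and the expected mutation yield of screening
    ``yield_length`` bp in the whole population (at the amplicon's own GC
    and rescaled to exon GC).  One ``average`` row is appended per EMS
    dose group; averages are taken over the rounded per-assay display
    values, matching the convention of published density tables.

    Returns a DataFrame; rows where the density is undefined (zero
    mutations) carry NA in every derived column.
    """
    if not assays:
        raise ValueError("at least one assay is required")
    rows = []
    for a in assays:
        row: dict[str, object] = {
            "gene": a.gene_name,
            "ems_pct": a.ems_dose,
            "length_bp": a.amplicon_length,
            "gc_pct": a.gc_percent,
            "mutations": a.mutations_detected,
            "screened": a.plants_screened,
            "population": a.population_size,
            "is_average": False,
        }
        if a.mutations_detected == 0:
            row.update(
                {k: pd.NA for k in (
                    "load_per_plant", "load_per_plant_norm",
                    "density_kb", "density_kb_norm",
                    "expected_per_kb", "expected_per_kb_exon_gc",
                )}
            )
        else:
            est = density_estimate(a, constants)
            bp_exon = normalize_bp_per_mutation(
                est.bp_per_mutation_raw, a.gc_percent, constants.exon_gc
            )
            row.update(
                {
                    "load_per_plant": est.mutations_per_plant_raw,
                    "load_per_plant_norm": est.mutations_per_plant_norm,
                    "density_kb": round_half_up(est.bp_per_mutation_raw / 1000.0),
                    "density_kb_norm": round_half_up(est.bp_per_mutation_norm / 1000.0),
                    "expected_per_kb": round_half_up(
                        expected_mutations(
                            a.population_size, yield_length, est.bp_per_mutation_raw
                        )
                    ),
                    "expected_per_kb_exon_gc": round_half_up(
                        expected_mutations(a.population_size, yield_length, bp_exon)
                    ),
                }
            )
        rows.append(row)
    table = pd.DataFrame(rows)

    derived_cols = [
        "load_per_plant", "load_per_plant_norm",
        "density_kb", "density_kb_norm",
        "expected_per_kb", "expected_per_kb_exon_gc",
    ]
    averages = []
    for dose, grp in table.groupby("ems_pct", sort=True):
        avg: dict[str, object] = {
            "gene": "average",
            "ems_pct": dose,
            "is_average": True,
        }
        for col in derived_cols:
            vals = grp[col].dropna()
            avg[col] = round_half_up(float(vals.mean())) if len(vals) else pd.NA
        averages.append(avg)
    return pd.concat([table, pd.DataFrame(averages)], ignore_index=True)


def class_composition_report(
    observed: dict[str, int], fractions: dict[str, float] | None = None
) -> ClassCompositionReport:
    """Observed mutation-class counts next to genetic-code expectations.

    ``fractions`` defaults to the 33/58/5-of-96 class fractions of the
    standard code.  No goodness-of-fit test is performed; the report is
    descriptive.
    """
    if not observed:
        raise ValueError("observed counts are empty")
    if any(v < 0 for v in observed.values()):
        raise ValueError("observed counts must be >= 0")
    if fractions is None:
        from .genetic_code import expected_class_fractions

        fractions = expected_class_fractions()
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    total = sum(observed.values())
    expected = {cls: total * f for cls, f in fractions.items()}
    return ClassCompositionReport(observed=dict(observed), expected=expected, total=total)


__all__ = [
    "SILENT", "MISSENSE", "NONSENSE", "NONSENSE_FRACTION",
    "ScreenAssay", "PopulationConstants", "DensityEstimate",
    "ClassCompositionReport", "DensityUndefinedError",
    "round_half_up", "bp_per_mutation", "format_density",
    "normalize_bp_per_mutation", "mutations_per_plant", "expected_mutations",
    "density_estimate", "p_at_least_one_nonsense", "saturation_fraction",
    "exon_budget", "backcross_load", "summarize_assays",
    "class_composition_report",
]
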