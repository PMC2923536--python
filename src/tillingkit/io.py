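"""File-format plumbing: FASTA, assay TSV tables, profiles, VCF-style export.

Conventions: all user-facing tables are TSV (UTF-8, '.' decimal), all
coordinates 1-based inclusive, rounding only at display time.
"""

from __future__ import annotations

import json
import warnings
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .genetic_code import CDSProfile
from .popsim import SimPlant
from .screen_stats import ScreenAssay

ASSAY_COLUMNS = {
    "gene": "gene_name",
    "ems_pct": "ems_dose",
    "length_bp": "amplicon_length",
    "gc_pct": "gc_percent",
    "mutations": "mutations_detected",
    "screened": "plants_screened",
    "population": "population_size",
}


class SchemaError(ValueError):
    """Raised when a tabular input is missing or mistypes a required column."""


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercased sequence), preserving order."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_assay_table(path) -> list[ScreenAssay]:
    """Read a TSV of raw screen-assay rows into typed ScreenAssay objects.

    Required columns: gene, ems_pct, length_bp, gc_pct, mutations,
    screened, population.  Lines starting with '#' are comments.  Rows
    with zero detected mutations load but trigger a warning (their
    density is undefined downstream).
    """
    try:
        table = pd.read_csv(path, sep="\t", comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SchemaError(f"{path}: cannot parse assay table: {exc}") from exc
    missing = set(ASSAY_COLUMNS) - set(table.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(sorted(missing))}")
    assays = []
    for i, row in table.iterrows():
        kwargs = {}
        for col, fieldname in ASSAY_COLUMNS.items():
            value = row[col]
            try:
                if fieldname == "gene_name":
                    kwargs[fieldname] = str(value)
                elif fieldname in ("ems_dose", "gc_percent"):
                    kwargs[fieldname] = float(value)
                else:
                    kwargs[fieldname] = int(value)
            except (TypeError, ValueError) as exc:
                raise SchemaError(
                    f"{path}: row {i + 1}, column {col!r}: "
                    f"cannot interpret {value!r}"
                ) from exc
        assay = ScreenAssay(**kwargs)
        if assay.mutations_detected == 0:
            warnings.warn(
                f"{path}: {assay.gene_name} has zero detected mutations; "
                "density will be undefined",
                stacklevel=2,
            )
        assays.append(assay)
    return assays


def load_brapa_assays() -> list[ScreenAssay]:
    """The packaged eight-assay B. rapa screen table (raw columns)."""
    ref = resources.files("tillingkit").joinpath("data/brapa_assays.tsv")
    with resources.as_file(ref) as path:
        return read_assay_table(path)


def load_brapa_mutation_classes() -> pd.DataFrame:
    """Packaged per-gene mutation-class counts and het/hom ratios."""
    ref = resources.files("tillingkit").joinpath("data/brapa_mutation_classes.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def profile_to_frame(profile: CDSProfile) -> pd.DataFrame:
    """Flatten a CDS profile into one row per possible EMS change."""
    rows = [
        {
            "seq_id": profile.sequence_id,
            "pos": pos,
            "codon": c.codon,
            "codon_pos": c.position,
            "from": c.from_base,
            "to": c.to_base,
            "new_codon": c.new_codon,
            "aa_from": c.aa_from,
            "aa_to": c.aa_to,
            "class": c.change_class,
        }
        for pos, c in profile.per_site_changes
    ]
    return pd.DataFrame(
        rows,
        columns=["seq_id", "pos", "codon", "codon_pos", "from", "to",
                 "new_codon", "aa_from", "aa_to", "class"],
    )


def write_profile_tsv(path, profile: CDSProfile) -> None:
    profile_to_frame(profile).to_csv(path, sep="\t", index=False)


def profile_summary_json(profile: CDSProfile) -> dict:
    return {
        "sequence_id": profile.sequence_id,
        "length_bp": profile.length_bp,
        "mutable_sites": profile.mutable_sites,
        "class_counts": profile.class_counts,
        "window_nonsense_density": [
            {"start": s, "end": e, "nonsense_sites": n}
            for s, e, n in profile.window_nonsense_density
        ],
    }


def write_mutations_tsv(path, plants: Sequence[SimPlant]) -> None:
    """Per-plant mutation table: plant_id, pos, ref, alt, zygosity."""
    with open(path, "w") as fh:
        fh.write("plant_id\tpos\tref\talt\tzygosity\n")
        for plant in plants:
            for rec in plant.records():
                fh.write("\t".join(map(str, rec)) + "\n")


def write_mutations_vcf(path, plants: Sequence[SimPlant], chrom: str = "sim_ref") -> None:
    """Minimal single-chromosome VCF-style export with one sample per plant.

    Genotypes: 0/1 for heterozygous, 1/1 for homozygous mutations.
    """
    variants: dict[int, tuple[str, str, dict[str, str]]] = {}
    for plant in plants:
        for _, pos, ref, alt, zyg in plant.records():
            gt = "0/1" if zyg == "het" else "1/1"
            if pos not in variants:
                variants[pos] = (ref, alt, {})
            variants[pos][2][plant.plant_id] = gt
    sample_ids = [p.plant_id for p in plants]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        for pos in sorted(variants):
            ref, alt, gts = variants[pos]
            row = [chrom, str(pos), ".", ref, alt, ".", "PASS", ".", "GT"]
            row += [gts.get(s, "0/0") for s in sample_ids]
            fh.write("\t".join(row) + "\n")


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
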