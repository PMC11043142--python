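"""Readers and writers for the tabular formats the pipeline touches.

Variant tables travel as TSV (one row per biallelic ALT) or as sites-only
VCF 4.2 with per-population ``AF_<POP>/AC_<POP>/AN_<POP>`` INFO keys.
Multi-allelic VCF rows are split into biallelic records.  Writers are
deterministic: identical inputs produce byte-identical files.
"""

from __future__ import annotations

import csv
import math
import re
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .datamodel import ControlGeneEntry, PopFrequency, VariantRecord
from .populations import GNOMAD_V21_EXOMES, PopulationLabel

_POP_COL = re.compile(r"^(AF|AC|AN)_([A-Za-z0-9]+)$")

VARIANT_FIXED_COLUMNS = ["contig", "pos", "ref", "alt", "rsid", "consequence", "cds_pos"]
MISSING = "."


def _fmt(value: object) -> str:
    if value is None:
        return MISSING
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _unknown_pop_error(code: str, panel: dict[str, PopulationLabel]) -> ValueError:
    known = ", ".join(sorted(panel))
    return ValueError(f"unknown population code {code!r}; known codes: {known}")


def read_variant_table(
    path: str | Path,
    format: str = "tsv",
    panel: dict[str, PopulationLabel] | None = None,
) -> list[VariantRecord]:
    """Read a variant table into :class:`VariantRecord` objects.

    Parameters
    ----------
    path
        File to read.
    format
        ``"tsv"`` (documented column layout) or ``"vcf-sites"``
        (sites-only VCF with per-population INFO keys).
    panel
        Population panel supplying default allele numbers; gnomAD v2.1
        exomes by default.  Columns/INFO keys naming a population outside
        the panel raise an error listing the known codes.
    """
    panel = panel if panel is not None else GNOMAD_V21_EXOMES
    if format == "tsv":
        return _read_tsv(Path(path), panel)
    if format == "vcf-sites":
        return _read_vcf_sites(Path(path), panel)
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'vcf-sites'")


def _read_tsv(path: Path, panel: dict[str, PopulationLabel]) -> list[VariantRecord]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        pop_codes: list[str] = []
        for col in header:
            m = _POP_COL.match(col)
            if m:
                code = m.group(2)
                if code not in panel:
                    raise _unknown_pop_error(code, panel)
                if code not in pop_codes:
                    pop_codes.append(code)
        records: list[VariantRecord] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(_row_to_record(row, pop_codes, panel))
            except (ValueError, KeyError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
    return records


def _opt(row: dict[str, str], col: str) -> str | None:
    raw = (row.get(col) or MISSING).strip()
    return None if raw == MISSING or raw == "" else raw


def _row_to_record(
    row: dict[str, str], pop_codes: list[str], panel: dict[str, PopulationLabel]
) -> VariantRecord:
    per_pop: dict[str, PopFrequency] = {}
    for code in pop_codes:
        af = _opt(row, f"AF_{code}")
        ac = _opt(row, f"AC_{code}")
        an = _opt(row, f"AN_{code}")
        if af is None and ac is None:
            continue
        per_pop[code] = PopFrequency(
            an=int(an) if an is not None else panel[code].allele_number,
            af=float(af) if af is not None else None,
            ac=int(ac) if ac is not None else None,
        )
    cds_pos = _opt(row, "cds_pos")
    cohort_ac = _opt(row, "cohort_ac")
    cohort_an = _opt(row, "cohort_an")
    return VariantRecord(
        contig=row["contig"],
        pos=int(row["pos"]),
        ref=row["ref"],
        alt=row["alt"],
        rsid=_opt(row, "rsid"),
        consequence=_opt(row, "consequence"),
        cds_pos=int(cds_pos) if cds_pos is not None else None,
        per_pop=per_pop,
        cohort_ac=int(cohort_ac) if cohort_ac is not None else None,
        cohort_an=int(cohort_an) if cohort_an is not None else None,
    )


def write_variant_table(
    records: list[VariantRecord],
    path: str | Path,
    panel: dict[str, PopulationLabel] | None = None,
) -> None:
    """Write records as TSV; reading the file back is lossless."""
    panel = panel if panel is not None else GNOMAD_V21_EXOMES
    codes = [c for c in panel if any(r.has_population(c) for r in records)]
    cols = list(VARIANT_FIXED_COLUMNS)
    for code in codes:
        cols += [f"AF_{code}", f"AC_{code}", f"AN_{code}"]
    cols += ["cohort_ac", "cohort_an"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for r in records:
            row = [r.contig, r.pos, r.ref, r.alt, _fmt(r.rsid),
                   _fmt(r.consequence), _fmt(r.cds_pos)]
            for code in codes:
                pf = r.per_pop.get(code)
                if pf is None:
                    row += [MISSING, MISSING, MISSING]
                else:
                    row += [_fmt(pf.af), _fmt(pf.ac), _fmt(pf.an)]
            row += [_fmt(r.cohort_ac), _fmt(r.cohort_an)]
            writer.writerow(row)


def _read_vcf_sites(path: Path, panel: dict[str, PopulationLabel]) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for key in vcf.header.info:
            m = _POP_COL.match(key)
            if m and m.group(2) not in panel:
                raise _unknown_pop_error(m.group(2), panel)
        pop_codes = sorted(
            {m.group(2) for key in vcf.header.info if (m := _POP_COL.match(key))}
        )
        for site in vcf:
            alts = site.alts or ()
            for i, alt in enumerate(alts):
                per_pop: dict[str, PopFrequency] = {}
                for code in pop_codes:
                    af = _info_a(site, f"AF_{code}", i, len(alts))
                    ac = _info_a(site, f"AC_{code}", i, len(alts))
                    an = site.info[f"AN_{code}"] if f"AN_{code}" in site.info else None
                    if af is None and ac is None:
                        continue
                    per_pop[code] = PopFrequency(
                        an=int(an) if an is not None else panel[code].allele_number,
                        af=float(af) if af is not None else None,
                        ac=int(ac) if ac is not None else None,
                    )
                csq = _info_a(site, "CONSEQUENCE", i, len(alts))
                cds = _info_a(site, "CDS_POS", i, len(alts))
                cac = _info_a(site, "COHORT_AC", i, len(alts))
                can = site.info["COHORT_AN"] if "COHORT_AN" in site.info else None
                records.append(
                    VariantRecord(
                        contig=site.chrom,
                        pos=site.pos,
                        ref=site.ref,
                        alt=alt,
                        rsid=None if site.id in (None, MISSING) else site.id,
                        consequence=None if csq is None else str(csq),
                        cds_pos=None if cds is None else int(cds),
                        per_pop=per_pop,
                        cohort_ac=None if cac is None else int(cac),
                        cohort_an=None if can is None else int(can),
                    )
                )
    return records


def _info_a(site: "pysam.VariantRecord", key: str, i: int, n_alts: int) -> object:
    """Fetch the i-th value of a Number=A INFO field, if present."""
    if key not in site.info:
        return None
    value = site.info[key]
    if isinstance(value, tuple):
        if len(value) != n_alts:
            raise ValueError(
                f"{site.chrom}:{site.pos}: INFO {key} has {len(value)} values "
                f"for {n_alts} ALT alleles"
            )
        value = value[i]
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return value


def write_vcf_sites(
    records: list[VariantRecord],
    path: str | Path,
    panel: dict[str, PopulationLabel] | None = None,
) -> None:
    """Write records as a sites-only VCF 4.2 file."""
    panel = panel if panel is not None else GNOMAD_V21_EXOMES
    codes = [c for c in panel if any(r.has_population(c) for r in records)]
    contigs = sorted({r.contig for r in records})
    lines = ["##fileformat=VCFv4.2"]
    for contig in contigs:
        lines.append(f"##contig=<ID={contig}>")
    for code in codes:
        lines.append(
            f'##INFO=<ID=AF_{code},Number=A,Type=Float,Description="Allele frequency, {code}">'
        )
        lines.append(
            f'##INFO=<ID=AC_{code},Number=A,Type=Integer,Description="Allele count, {code}">'
        )
        lines.append(
            f'##INFO=<ID=AN_{code},Number=1,Type=Integer,Description="Allele number, {code}">'
        )
    lines += [
        '##INFO=<ID=CONSEQUENCE,Number=A,Type=String,Description="Molecular consequence">',
        '##INFO=<ID=CDS_POS,Number=A,Type=Integer,Description="1-based position in CDS">',
        '##INFO=<ID=COHORT_AC,Number=A,Type=Integer,Description="Cohort allele count">',
        '##INFO=<ID=COHORT_AN,Number=1,Type=Integer,Description="Cohort allele number">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for r in sorted(records, key=lambda v: (v.contig, v.pos, v.alt)):
        info: list[str] = []
        for code in codes:
            pf = r.per_pop.get(code)
            if pf is None:
                continue
            if pf.af is not None:
                info.append(f"AF_{code}={pf.af:.6g}")
            if pf.ac is not None:
                info.append(f"AC_{code}={pf.ac}")
            info.append(f"AN_{code}={pf.an}")
        if r.consequence is not None:
            info.append(f"CONSEQUENCE={r.consequence}")
        if r.cds_pos is not None:
            info.append(f"CDS_POS={r.cds_pos}")
        if r.cohort_ac is not None:
            info.append(f"COHORT_AC={r.cohort_ac}")
        if r.cohort_an is not None:
            info.append(f"COHORT_AN={r.cohort_an}")
        lines.append(
            "\t".join(
                [r.contig, str(r.pos), r.rsid or MISSING, r.ref, r.alt,
                 MISSING, MISSING, ";".join(info) or MISSING]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_control_table(path: str | Path) -> list[ControlGeneEntry]:
    """Read a control-gene TSV: gene_symbol, cds_length, count_<POP>..."""
    df = pd.read_csv(path, sep="\t")
    count_cols = [c for c in df.columns if c.startswith("count_")]
    entries = []
    for _, row in df.iterrows():
        entries.append(
            ControlGeneEntry(
                gene_symbol=str(row["gene_symbol"]),
                cds_length=int(row["cds_length"]),
                rare_missense_count={
                    c.removeprefix("count_"): int(row[c]) for c in count_cols
                },
            )
        )
    return entries


def write_control_table(entries: list[ControlGeneEntry], path: str | Path) -> None:
    codes = sorted({c for e in entries for c in e.rare_missense_count})
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_symbol", "cds_length"] + [f"count_{c}" for c in codes])
        for e in entries:
            writer.writerow([e.gene_symbol, e.cds_length] + [e.count(c) for c in codes])


def write_bed(regions, path: str | Path, chrom: str) -> None:
    """Write a region set as BED6 in CDS coordinates (0-based half-open).

    The score column is the mean window density of the region scaled by
    1000 and clamped to integer [0, 1000].
    """
    with open(path, "w", newline="") as fh:
        for start, end, label, mean_density in regions:
            score = max(0, min(1000, int(round(mean_density * 1000))))
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\t{score}\t.\n")


def write_genotype_matrix(genotypes, path: str | Path) -> None:
    """Write dosages as TSV: one row per individual, one column per variant."""
    df = pd.DataFrame(
        genotypes.dosages,
        index=list(genotypes.individuals),
        columns=list(genotypes.variant_ids),
    )
    df.index.name = "individual"
    df.to_csv(path, sep="\t")


def read_genotype_matrix(path: str | Path):
    """Read a dosage TSV back into a :class:`~varburden.ld.GenotypeMatrix`.

    Phasing is not representable in the dosage TSV, so the result carries
    dosages only.
    """
    from .ld import GenotypeMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeMatrix(
        individuals=tuple(str(i) for i in df.index),
        variant_ids=tuple(str(c) for c in df.columns),
        dosages=df.to_numpy(dtype=np.int64),
    )


def write_results(tables: dict, out_dir: str | Path) -> dict[str, str]:
    """Write a pipeline result set as deterministic TSV/BED files.

    Recognized keys: ``variants`` (records), ``enrichment``/``burden``/
    ``percentile`` (DataFrames), ``density`` (pop -> DensityProfile),
    ``regions`` (pop -> RegionSet), ``similarity`` (DataFrame), ``ld``
    (LDMatrix), ``genotypes`` (GenotypeMatrix), ``controls`` (entries).
    Returns a manifest mapping logical names to written file paths.
    Identical inputs yield byte-identical files.
    """
    from .density import region_bed_rows

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def _frame(name: str, df: pd.DataFrame, fname: str) -> None:
        path = out / fname
        df.to_csv(path, sep="\t", index=False, float_format="%.10g",
                  lineterminator="\n")
        manifest[name] = str(path)

    if "variants" in tables:
        path = out / "variants.tsv"
        write_variant_table(tables["variants"], path, panel=tables.get("panel"))
        manifest["variants"] = str(path)
    if "controls" in tables:
        path = out / "controls.tsv"
        write_control_table(tables["controls"], path)
        manifest["controls"] = str(path)
    for key, fname in (("enrichment", "enrichment.tsv"), ("burden", "burden.tsv"),
                       ("percentile", "percentile.tsv"), ("similarity", "similarity.tsv")):
        if key in tables:
            _frame(key, tables[key], fname)
    if "density" in tables:
        for code, profile in tables["density"].items():
            df = pd.DataFrame(
                {
                    "cds_pos": np.arange(1, profile.cds_length + 1),
                    "density": profile.density,
                    "threshold": profile.threshold,
                    "label": profile.labels if profile.threshold is not None else MISSING,
                }
            )
            _frame(f"density_{code}", df, f"density_{code}.tsv")
    if "regions" in tables:
        for code, (regions, profile) in tables["regions"].items():
            path = out / f"regions_{code}.bed"
            write_bed(region_bed_rows(regions, profile), path, chrom=tables.get("chrom", "CDS"))
            manifest[f"regions_{code}"] = str(path)
    if "ld" in tables:
        ldm = tables["ld"]
        df = pd.DataFrame(ldm.r2, index=list(ldm.variant_ids),
                          columns=list(ldm.variant_ids))
        df.index.name = "variant"
        path = out / "ld.tsv"
        df.to_csv(path, sep="\t", float_format="%.10g", lineterminator="\n")
        manifest["ld"] = str(path)
    if "genotypes" in tables:
        path = out / "genotypes.tsv"
        write_genotype_matrix(tables["genotypes"], path)
        manifest["genotypes"] = str(path)
    return manifest


def fixture_path(name: str = "fmd_otog_cohort.tsv") -> Path:
    """Path to a packaged data fixture."""
    return Path(__file__).parent / "data" / name


def load_fmd_cohort_fixture() -> list[VariantRecord]:
    """The 13 rare missense variants of the familial MD cohort.

    Per-population allele frequencies are the published gnomAD v2.1 exome
    values; cohort counts are out of 200 alleles (100 probands).
    """
    return read_variant_table(fixture_path(), format="tsv")
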