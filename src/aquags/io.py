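"""Readers and writers for the pipeline's exchange formats.

Genotypes travel as biallelic VCF (GT field, read through cyvcf2) or as the
simpler dosage-TSV dialect: a header row ``id<TAB><snp ids...>``, one
individual per row with values in {0, 1, 2, NA}, plus a sidecar map TSV with
columns ``snp chrom pos``. Phenotypes are TSV keyed by individual id. Gene
annotation is GFF3 (parsed with gffutils). GRMs are TSV matrices with id
headers and a JSON sidecar.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .grm import GRM
from .panel import GenotypePanel, PanelError

__all__ = [
    "read_genotypes",
    "read_vcf",
    "write_vcf",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_phenotypes",
    "write_phenotypes",
    "read_grm_tsv",
    "write_grm_tsv",
    "read_gff3_genes",
    "write_gff3",
]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    pass


# ------------------------------------------------------------------- VCF
def write_vcf(panel: GenotypePanel, path: str | Path, source: str = "aquags") -> None:
    """Write the panel as a minimal biallelic VCF (GT only).

    Dosages must be integral (0/1/2) or missing; imputed real-valued panels
    cannot be represented as genotypes.
    """
    dos = panel.dosages
    finite = dos[np.isfinite(dos)]
    if finite.size and np.any(finite != np.round(finite)):
        raise FormatError("non-integer dosages cannot be written as VCF genotypes")
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        for chrom in dict.fromkeys(panel.chromosomes):
            max_pos = int(panel.positions_bp[panel.chromosomes == chrom].max())
            fh.write(f"##contig=<ID={chrom},length={max_pos + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.individual_ids) + "\n")
        for j in range(panel.n_snps):
            calls = [
                "./." if not np.isfinite(d) else gt_map[int(round(d))]
                for d in dos[:, j]
            ]
            fh.write(
                f"{panel.chromosomes[j]}\t{panel.positions_bp[j]}\t{panel.snp_ids[j]}"
                "\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )
    logger.info("wrote VCF %s (%d x %d)", path, panel.n_individuals, panel.n_snps)


def read_vcf(path: str | Path) -> GenotypePanel:
    """Read a biallelic-SNP VCF into a panel (alternate-allele dosages)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individual_ids = list(vcf.samples)
    rows, snp_ids, chroms, positions = [], [], [], []
    rejected = []
    for v in vcf:
        if len(v.ALT) != 1:
            rejected.append(v.ID or f"{v.CHROM}:{v.POS}")
            continue
        # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
        gt = np.asarray(v.gt_types)
        dose = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
        rows.append(dose)
        snp_ids.append(v.ID or f"{v.CHROM}:{v.POS}")
        chroms.append(v.CHROM)
        positions.append(v.POS)
    if rejected:
        raise FormatError(f"multi-allelic records not supported: {rejected[:10]}")
    if not rows:
        raise FormatError(f"no usable variant records in {path}")
    return GenotypePanel(
        dosages=np.asarray(rows).T,
        individual_ids=individual_ids,
        snp_ids=snp_ids,
        chromosomes=np.asarray(chroms, dtype=object),
        positions_bp=np.asarray(positions, dtype=np.int64),
    )


# ------------------------------------------------------------ dosage TSV
def write_dosage_tsv(panel: GenotypePanel, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.dosage.tsv`` and the sidecar ``<prefix>.map.tsv``."""
    dosage_path = Path(str(prefix) + ".dosage.tsv")
    map_path = Path(str(prefix) + ".map.tsv")
    df = pd.DataFrame(panel.dosages, index=panel.individual_ids, columns=panel.snp_ids)
    df.index.name = "id"
    df.to_csv(dosage_path, sep="\t", na_rep="NA")
    pd.DataFrame(
        {"snp": panel.snp_ids, "chrom": panel.chromosomes, "pos": panel.positions_bp}
    ).to_csv(map_path, sep="\t", index=False)
    return dosage_path, map_path


def read_dosage_tsv(dosage_path: str | Path, map_path: str | Path) -> GenotypePanel:
    df = pd.read_csv(dosage_path, sep="\t", index_col=0, na_values=["NA"])
    if df.index.duplicated().any():
        raise FormatError("duplicated individual ids in dosage TSV")
    if pd.Index(df.columns).duplicated().any():
        raise FormatError("duplicated SNP ids in dosage TSV")
    gmap = pd.read_csv(map_path, sep="\t", dtype={"snp": str, "chrom": str, "pos": np.int64})
    required = {"snp", "chrom", "pos"}
    if not required.issubset(gmap.columns):
        raise FormatError(f"map TSV must have columns {sorted(required)}")
    gmap = gmap.set_index("snp").reindex([str(c) for c in df.columns])
    if gmap["pos"].isna().any():
        missing = gmap.index[gmap["pos"].isna()].tolist()
        raise FormatError(f"map TSV lacks entries for SNPs: {missing[:5]}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric dosage value: {exc}") from exc
    return GenotypePanel(
        dosages=values,
        individual_ids=[str(i) for i in df.index],
        snp_ids=[str(c) for c in df.columns],
        chromosomes=gmap["chrom"].to_numpy(dtype=object),
        positions_bp=gmap["pos"].to_numpy(dtype=np.int64),
    )


def read_genotypes(path: str | Path, fmt: str = "auto", map_path: str | Path | None = None) -> GenotypePanel:
    """Dispatch on format: ``vcf`` or ``dosage_tsv`` (auto by extension)."""
    path = Path(path)
    if fmt == "auto":
        fmt = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} or path.name.endswith(".vcf.gz") else "dosage_tsv"
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "dosage_tsv":
        if map_path is None:
            map_path = Path(str(path).replace(".dosage.tsv", ".map.tsv"))
        return read_dosage_tsv(path, map_path)
    raise FormatError(f"unknown genotype format {fmt!r}")


# ------------------------------------------------------------- phenotypes
def read_phenotypes(path: str | Path, panel: GenotypePanel | None = None) -> pd.DataFrame:
    """Read a phenotype TSV (first column id, numeric trait columns, NA allowed).

    When a panel is given, rows are matched to its individuals by exact id;
    unmatched phenotype rows are dropped with a warning and an error is
    raised if no ids overlap. A Table-1-shaped per-trait mean/SD summary is
    logged.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError("phenotype TSV needs an id column plus at least one trait")
    df = df.set_index(df.columns[0])
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise FormatError(f"non-numeric value in column {col!r}, row {row!r}") from exc
    if panel is not None:
        overlap = df.index.intersection(panel.individual_ids)
        if overlap.empty:
            raise FormatError("no phenotype ids overlap the genotype panel")
        dropped = len(df) - len(overlap)
        if dropped:
            logger.warning("%d phenotyped individual(s) absent from panel; excluded", dropped)
        df = df.reindex(panel.individual_ids)
    summary = df.agg(["mean", "std"]).T
    logger.info("phenotype summary (mean +/- SD):\n%s", summary.to_string())
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="id", na_rep="NA")


# -------------------------------------------------------------------- GRM
def write_grm_tsv(grm: GRM, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(grm.values, index=grm.individual_ids, columns=grm.individual_ids).to_csv(
        path, sep="\t", index_label="id"
    )
    sidecar = {
        "denominator": grm.denominator,
        "n": grm.n,
        "m": int(np.asarray(grm.allele_freqs).size),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_grm_tsv(path: str | Path) -> GRM:
    df = pd.read_csv(path, sep="\t", index_col=0)
    sidecar_path = Path(str(path) + ".json")
    denom = np.nan
    freqs = np.empty(0)
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        denom = float(meta.get("denominator", np.nan))
    return GRM(
        values=df.to_numpy(dtype=float),
        individual_ids=[str(i) for i in df.index],
        denominator=denom,
        allele_freqs=freqs,
    )


# ------------------------------------------------------------------- GFF3
def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    """Extract gene records (1-based inclusive) from a GFF3 file.

    Returns a frame with columns chrom/start/end/strand/gene_id/name.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type("gene"):
        rows.append(
            {
                "chrom": feat.seqid,
                "start": feat.start,
                "end": feat.end,
                "strand": feat.strand,
                "gene_id": feat.id,
                "name": (feat.attributes.get("Name") or [feat.id])[0],
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id", "name"])


def write_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    """Write a minimal gene-only GFF3 (inverse of :func:`read_gff3_genes`)."""
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            attrs = f"ID={g['gene_id']};Name={g.get('name', g['gene_id'])}"
            fh.write(
                f"{g['chrom']}\taquags\tgene\t{int(g['start'])}\t{int(g['end'])}\t.\t"
                f"{g.get('strand', '+')}\t.\t{attrs}\n"
            )
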