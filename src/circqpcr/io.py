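"""Readers and writers for every tabular artifact in the pipeline.

All writers can prepend a ``# key: value`` metadata header (version, seed,
config hash); all readers skip ``#`` comment lines, so round-trips are
exact. Count tables follow a CIRI2/CIRIquant-like dialect: tab-separated,
one back-spliced junction per row, ids of the form ``chrom:start|end`` with
1-based inclusive coordinates.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .types import (
    BsjCountTable,
    CT_COLUMNS,
    GeneCountTable,
    PrimerMap,
    ValidationError,
    parse_circ_id,
    validate_ct_frame,
)

#: Strings treated as non-detect in the ``ct`` column.
NON_DETECT_TOKENS = {"NA", "Undetermined", "undetermined", ""}


def _write_with_metadata(df: pd.DataFrame, path, sep: str, metadata: dict | None,
                         index: bool = False) -> None:
    path = Path(path)
    try:
        with open(path, "w") as fh:
            if metadata:
                for k, v in metadata.items():
                    fh.write(f"# {k}: {v}\n")
            df.to_csv(fh, sep=sep, index=index)
    except OSError as exc:
        raise ValidationError(f"cannot write {path}: {exc}") from exc


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for output provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


def standard_metadata(seed: int | None = None, config: dict | None = None) -> dict:
    md = {"package": f"circqpcr {__version__}"}
    if seed is not None:
        md["seed"] = seed
    if config is not None:
        md["config_hash"] = config_hash(config)
    return md


# ---------------------------------------------------------------------------
# Ct tables and primer maps


def read_ct_table(path, primer_map: PrimerMap | None = None) -> pd.DataFrame:
    """Read a long-format Ct CSV.

    Expected header: ``animal,litter,sex,genotype,run,primer,replicate,ct``;
    ``NA``/``Undetermined`` (or empty) in ``ct`` mark non-detects and load as
    NaN. Unknown primers (when a primer map is given), schema violations and
    duplicate ``(animal, primer, run, replicate)`` keys are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(
        path,
        comment="#",
        dtype={c: str for c in ("animal", "litter", "sex", "genotype", "run", "primer")},
        na_values=sorted(NON_DETECT_TOKENS),
        keep_default_na=False,
    )
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    try:
        df["replicate"] = df["replicate"].astype(int)
        df["ct"] = pd.to_numeric(df["ct"], errors="raise")
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: malformed numeric column: {exc}") from exc
    extra = [c for c in df.columns if c not in CT_COLUMNS]
    out = validate_ct_frame(df, primer_map)
    for c in extra:
        out[c] = df[c]
    return out


def write_ct_table(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    df = df.copy()
    df["ct"] = df["ct"].map(lambda x: "Undetermined" if pd.isna(x) else repr(float(x)))
    _write_with_metadata(df, path, ",", metadata)


def read_primer_map(path) -> PrimerMap:
    """Read a primer annotation CSV (columns: primer, species_role,
    host_gene, paired_canonical, efficiency)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path, comment="#", dtype={"paired_canonical": str})
    return PrimerMap.from_frame(df)


def write_primer_map(pm: PrimerMap, path, metadata: dict | None = None) -> None:
    _write_with_metadata(pm.to_frame(), path, ",", metadata)


# ---------------------------------------------------------------------------
# Count tables (CIRI2/CIRIquant-like TSV dialect)


def _read_samples(samples_path) -> pd.Series:
    df = pd.read_csv(samples_path, sep="\t", comment="#", dtype=str)
    if not {"sample", "genotype"} <= set(df.columns):
        raise ValidationError(f"{samples_path}: needs columns 'sample' and 'genotype'")
    if df["sample"].duplicated().any():
        raise ValidationError(f"{samples_path}: duplicate sample labels")
    return df.set_index("sample")["genotype"]


def _int_counts(df: pd.DataFrame, what: str, path) -> pd.DataFrame:
    vals = df.to_numpy()
    try:
        as_float = vals.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric {what} count: {exc}") from exc
    if not np.allclose(as_float, np.round(as_float)):
        raise ValidationError(f"{path}: non-integer {what} counts")
    if (as_float < 0).any():
        raise ValidationError(f"{path}: negative {what} counts")
    return pd.DataFrame(as_float.astype(np.int64), index=df.index, columns=df.columns)


def read_count_tables(bsj_path, gene_path, samples_path) -> tuple[BsjCountTable, GeneCountTable]:
    """Read paired BSJ and host-gene count TSVs plus a sample sheet.

    BSJ table columns: ``circ_id  host_gene  strand  <sample...>``; gene
    table: ``gene_id  <sample...>``; sample sheet: ``sample  genotype``.
    Every circRNA's host gene must be present in the gene table.
    """
    for p in (bsj_path, gene_path, samples_path):
        if not Path(p).exists():
            raise ValidationError(f"no such file: {p}")
    groups = _read_samples(samples_path)

    bsj_raw = pd.read_csv(bsj_path, sep="\t", comment="#", dtype={"circ_id": str})
    for col in ("circ_id", "host_gene", "strand"):
        if col not in bsj_raw.columns:
            raise ValidationError(f"{bsj_path}: missing column {col!r}")
    sample_cols = [c for c in bsj_raw.columns if c not in ("circ_id", "host_gene", "strand")]
    if not sample_cols:
        raise ValidationError(f"{bsj_path}: no sample columns")
    meta_rows = []
    for cid in bsj_raw["circ_id"]:
        chrom, start, end = parse_circ_id(str(cid))
        meta_rows.append({"circ_id": cid, "chrom": chrom, "start": start, "end": end})
    meta = pd.DataFrame(meta_rows).set_index("circ_id")
    meta["host_gene"] = bsj_raw.set_index("circ_id")["host_gene"]
    meta["strand"] = bsj_raw.set_index("circ_id")["strand"]
    counts = _int_counts(bsj_raw.set_index("circ_id")[sample_cols], "BSJ", bsj_path)

    gene_raw = pd.read_csv(gene_path, sep="\t", comment="#", dtype={"gene_id": str})
    if "gene_id" not in gene_raw.columns:
        raise ValidationError(f"{gene_path}: missing column 'gene_id'")
    gcols = [c for c in gene_raw.columns if c != "gene_id"]
    gene_counts = _int_counts(gene_raw.set_index("gene_id")[gcols], "gene", gene_path)

    if set(sample_cols) != set(gcols):
        raise ValidationError("BSJ and gene tables have different sample columns")
    missing_samples = set(sample_cols) - set(groups.index)
    if missing_samples:
        raise ValidationError(f"samples missing from sample sheet: {sorted(missing_samples)}")
    missing_hosts = sorted(set(meta["host_gene"]) - set(gene_counts.index))
    if missing_hosts:
        raise ValidationError(
            f"host genes absent from gene table: {missing_hosts}"
        )

    bsj = BsjCountTable(counts=counts, meta=meta, sample_groups=groups.loc[sample_cols])
    genes = GeneCountTable(counts=gene_counts[sample_cols], sample_groups=groups.loc[sample_cols])
    return bsj, genes


def write_count_tables(bsj: BsjCountTable, genes: GeneCountTable, bsj_path, gene_path,
                       samples_path, metadata: dict | None = None) -> None:
    out = bsj.meta[["host_gene", "strand"]].join(bsj.counts).reset_index()
    out = out.rename(columns={"index": "circ_id"})
    _write_with_metadata(out, bsj_path, "\t", metadata)
    gdf = genes.counts.reset_index().rename(columns={"index": "gene_id"})
    if gdf.columns[0] != "gene_id":
        gdf = gdf.rename(columns={gdf.columns[0]: "gene_id"})
    _write_with_metadata(gdf, gene_path, "\t", metadata)
    sdf = bsj.sample_groups.rename_axis("sample").reset_index()
    _write_with_metadata(sdf, samples_path, "\t", metadata)


# ---------------------------------------------------------------------------
# Generic result tables and posterior draws


def write_result_table(results: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a results CSV with deterministic column order.

    Rejects empty tables; round-trips exactly through
    :func:`read_result_table`.
    """
    if results is None or len(results) == 0:
        raise ValidationError("refusing to write an empty result table")
    _write_with_metadata(results, path, ",", metadata)


def read_result_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    return pd.read_csv(path, comment="#")


def write_posterior(posterior, draws_path, diagnostics_path=None,
                    metadata: dict | None = None) -> None:
    """Persist posterior draws (long CSV: chain, draw, parameter, value) and
    optionally a per-parameter diagnostics CSV (R-hat, ESS).

    The factor levels (with reference levels first) are embedded in a
    ``# coords:`` header line so estimands can be recomputed after reload.
    """
    md = dict(metadata or {})
    md["coords"] = json.dumps(posterior.coords)
    _write_with_metadata(posterior.to_long_dataframe(), draws_path, ",", md)
    if diagnostics_path is not None:
        _write_with_metadata(posterior.diagnostics_frame(), diagnostics_path, ",", metadata)


def read_posterior(draws_path):
    """Rebuild a :class:`~circqpcr.model.PosteriorSamples` from a draws CSV."""
    from .model import PosteriorSamples

    draws_path = Path(draws_path)
    if not draws_path.exists():
        raise ValidationError(f"no such file: {draws_path}")
    coords = None
    with open(draws_path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if body.startswith("coords:"):
                coords = json.loads(body[len("coords:"):].strip())
    df = pd.read_csv(draws_path, comment="#")
    for col in ("chain", "draw", "parameter", "value"):
        if col not in df.columns:
            raise ValidationError(f"{draws_path}: missing column {col!r}")
    return PosteriorSamples.from_long_dataframe(df, coords=coords)
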