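"""File formats and configuration.

On-disk conventions:

* regions: BED (tab-separated, 0-based half-open; columns chrom, start,
  end, name, optional gene_density as score column 5). A reader flag accepts
  1-based inclusive coordinates for tables exported from such tools.
* traces: CSV with columns ``cell_id, copy_id, readout_id, x_nm, y_nm,
  z_nm, quality``; missing loci are rows with empty coordinate fields (or
  simply absent rows — both round-trip).
* codebooks: CSV with columns ``gene_id, word`` (16-character bitstring).
* expression matrices: CSV (cells x genes, cell_id index) and MatrixMarket.
* configuration: YAML; every run records its config hash and seeds.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import ChromatinTrace, Codebook, ExpressionMatrix, GenomicRegion

__all__ = [
    "read_regions",
    "write_regions",
    "read_traces",
    "write_traces",
    "read_codebook",
    "write_codebook",
    "write_expression",
    "read_expression",
    "load_config",
    "config_hash",
]

TRACE_COLUMNS = ["cell_id", "copy_id", "readout_id", "x_nm", "y_nm", "z_nm", "quality"]


def read_regions(path: str | Path, one_based_inclusive: bool = False) -> list[GenomicRegion]:
    """Read genomic regions from a BED-like file.

    Columns: chrom, start, end, name[, gene_density]. Malformed lines and
    duplicate region ids are errors reported with their line number.
    """
    regions: list[GenomicRegion] = []
    seen: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected at least 4 tab-separated fields")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from err
            if one_based_inclusive:
                start -= 1
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end ({end}) must exceed start ({start})")
            if name in seen:
                raise ValueError(
                    f"{path}:{lineno}: duplicate region id {name!r} (first at line {seen[name]})"
                )
            seen[name] = lineno
            density = None
            if len(fields) >= 5 and fields[4] not in ("", "."):
                density = float(fields[4])
            regions.append(
                GenomicRegion(chrom=chrom, start=start, end=end, region_id=name, gene_density=density)
            )
    return regions


def write_regions(regions: list[GenomicRegion], path: str | Path) -> None:
    """Write regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            density = "." if r.gene_density is None else repr(r.gene_density)
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t{density}\n")


def write_traces(traces: list[ChromatinTrace], path: str | Path, units: str = "nm") -> None:
    """Write traces to CSV; missing loci get empty coordinate fields."""
    if units != "nm":
        raise ValueError("trace files are written in nm")
    rows = []
    for t in traces:
        for r in range(t.n_loci):
            x, y, z = t.positions[r]
            q = np.nan if t.quality is None else t.quality[r]
            rows.append(
                {
                    "cell_id": t.cell_id,
                    "copy_id": t.copy_id,
                    "readout_id": r,
                    "x_nm": x,
                    "y_nm": y,
                    "z_nm": z,
                    "quality": q,
                }
            )
    # %.17g keeps float64 coordinates bit-exact across the round trip
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_traces(path: str | Path, units: str = "nm") -> list[ChromatinTrace]:
    """Read traces from CSV (lossless round-trip including missing loci)."""
    if units != "nm":
        raise ValueError("trace files carry nm coordinates; pass units='nm'")
    df = pd.read_csv(path, float_precision="round_trip")
    unknown = set(df.columns) - set(TRACE_COLUMNS)
    if unknown:
        raise ValueError(f"unknown trace columns: {sorted(unknown)}")
    missing = {"cell_id", "copy_id", "readout_id"} - set(df.columns)
    if missing:
        raise ValueError(f"missing trace columns: {sorted(missing)}")
    n_loci = int(df["readout_id"].max()) + 1 if len(df) else 0
    traces = []
    for (cell, copy), grp in df.groupby(["cell_id", "copy_id"], sort=True):
        pos = np.full((n_loci, 3), np.nan)
        quality = np.full(n_loci, np.nan)
        for _, row in grp.iterrows():
            r = int(row["readout_id"])
            pos[r] = (row.get("x_nm", np.nan), row.get("y_nm", np.nan), row.get("z_nm", np.nan))
            quality[r] = row.get("quality", np.nan)
        traces.append(
            ChromatinTrace(cell_id=int(cell), copy_id=int(copy), positions=pos, quality=quality)
        )
    return traces


def write_codebook(codebook: Codebook, path: str | Path) -> None:
    rows = [
        {"gene_id": g, "word": "".join(str(b) for b in w)}
        for g, w in zip(codebook.genes, codebook.words)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_codebook(path: str | Path) -> Codebook:
    from .decoding import validate_codebook

    df = pd.read_csv(path, dtype={"word": str})
    if not {"gene_id", "word"} <= set(df.columns):
        raise ValueError("codebook CSV needs columns gene_id, word")
    return validate_codebook(dict(zip(df["gene_id"], df["word"])))


def write_expression(matrix: ExpressionMatrix, path_csv: str | Path, path_mtx: str | Path | None = None) -> None:
    df = pd.DataFrame(matrix.counts, index=matrix.cell_ids, columns=matrix.genes)
    df.index.name = "cell_id"
    df["qc_flag"] = [matrix.flags.get(c, "") for c in matrix.cell_ids]
    df.to_csv(path_csv)
    if path_mtx is not None:
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(str(path_mtx), csr_matrix(matrix.counts))


def read_expression(path_csv: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path_csv, index_col="cell_id")
    flags_col = df.pop("qc_flag") if "qc_flag" in df.columns else None
    flags = {}
    if flags_col is not None:
        flags = {int(c): f for c, f in flags_col.items() if isinstance(f, str) and f}
    return ExpressionMatrix(
        counts=df.to_numpy(dtype=int),
        cell_ids=[int(c) for c in df.index],
        genes=list(df.columns),
        flags=flags,
    )


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration and validate the common fields."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    thresholds = cfg.get("thresholds", {})
    for key, default in (("contact_nm", 150.0), ("association_nm", 200.0)):
        thresholds.setdefault(key, default)
        if thresholds[key] <= 0:
            raise ValueError(f"threshold {key} must be positive")
    cfg["thresholds"] = thresholds
    cfg.setdefault("seed", 0)
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
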