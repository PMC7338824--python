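"""File readers and writers: NIfTI volumes, TSV omics/trait tables, reports.

All tabular artifacts are tab-delimited UTF-8 with one header row, preceded by
``#``-prefixed metadata lines embedding the configuration hash and seed that
produced the file.  Floats are written at full round-trip precision.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import READERS, OmicsMatrix, PipelineConfig, SegmentedVolume, TraitSpec, TraitTable
from .errors import (
    EmptyMaskError,
    MaskFormatError,
    ParameterError,
    RadioprotError,
    ShapeMismatchError,
)

logger = logging.getLogger("radioprot")

_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# metadata headers

def _meta_lines(config: PipelineConfig | None, seed: int | None) -> str:
    h = config.config_hash() if config is not None else "none"
    s = config.seed if (seed is None and config is not None) else seed
    return f"# config_hash={h}\n# seed={s}\n"


def write_tsv(df: pd.DataFrame, path, config: PipelineConfig | None = None,
              seed: int | None = None, index_label: str | None = None) -> None:
    """Write a DataFrame as TSV with metadata comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_lines(config, seed))
        df.to_csv(fh, sep="\t", float_format=_FLOAT_FMT, index_label=index_label)


def read_tsv(path, index_col: int | str | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


# ---------------------------------------------------------------------------
# segmented volumes

def relabel_sites(mask: np.ndarray) -> tuple[np.ndarray, dict[int, int]]:
    """Compact nonzero mask labels to 1..S; returns (new mask, old->new map).

    Site indices are positional in all downstream math, so gaps in the label
    set (e.g. {1, 3}) carry no information and are removed.
    """
    labels = np.unique(mask[mask > 0])
    mapping = {int(old): new for new, old in enumerate(labels, start=1)}
    if all(k == v for k, v in mapping.items()):
        return mask.astype(np.int32), mapping
    out = np.zeros_like(mask, dtype=np.int32)
    for old, new in mapping.items():
        out[mask == old] = new
    logger.info("relabeled mask sites: %s", mapping)
    return out, mapping


def read_segmented_volume(intensity_path, mask_path, patient_id: str | None = None) -> SegmentedVolume:
    """Load an intensity NIfTI and a site-label NIfTI into a SegmentedVolume.

    Mask labels are cast to integers losslessly and compacted to 1..S (the
    relabeling is logged).  Raises on shape mismatch, non-integer labels, or
    an empty mask.
    """
    img = nib.load(str(intensity_path))
    msk = nib.load(str(mask_path))
    intens = np.asarray(img.dataobj, dtype=float)
    mask = np.asarray(msk.dataobj)
    if intens.shape != mask.shape:
        raise ShapeMismatchError(f"intensity shape {intens.shape} != mask shape {mask.shape}")
    if not np.allclose(mask, np.round(mask)):
        raise MaskFormatError(f"mask {mask_path} contains non-integer values")
    mask = np.round(mask).astype(np.int32)
    if not np.any(mask > 0):
        raise EmptyMaskError(f"mask {mask_path} has no foreground voxels")
    mask, _ = relabel_sites(mask)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    pid = patient_id if patient_id is not None else Path(intensity_path).name.split(".")[0]
    return SegmentedVolume(intensities=intens, spacing=spacing, mask=mask, patient_id=pid)


def write_segmented_volume(volume: SegmentedVolume, intensity_path, mask_path,
                           config: PipelineConfig | None = None, seed: int | None = None) -> None:
    """Write the intensity grid and mask as a NIfTI pair (spacing in the affine)."""
    affine = np.diag(list(volume.spacing) + [1.0])
    descrip = f"cfg:{config.config_hash() if config else 'none'} seed:{seed if seed is not None else (config.seed if config else 'na')}"
    for arr, path, dtype in ((volume.intensities, intensity_path, np.float32),
                             (volume.mask, mask_path, np.int16)):
        img = nib.Nifti1Image(np.asarray(arr, dtype=dtype), affine)
        img.header["descrip"] = descrip.encode()[:79]
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        nib.save(img, str(path))


def write_feature_volume(data: np.ndarray, spacing, path,
                         config: PipelineConfig | None = None, seed: int | None = None) -> None:
    """Write a 3D or 4D (x,y,z,channel) float volume as NIfTI."""
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    descrip = f"cfg:{config.config_hash() if config else 'none'} seed:{seed}"
    img.header["descrip"] = descrip.encode()[:79]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# omics tables

def read_omics_table(path, kind: str) -> OmicsMatrix:
    """Read a gene x sample TSV/CSV into an OmicsMatrix.

    Rows sharing a gene identifier are averaged element-wise with missing
    values excluded from each mean; a row that is entirely missing is kept
    (all-NaN) with a warning.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, comment="#", index_col=0)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    no_numeric = numeric.isna().all().all() and not df.empty and df.notna().any().any()
    if numeric.shape[1] == 0 or no_numeric:
        raise ParameterError(f"{path}: no numeric sample columns")
    if numeric.index.has_duplicates:
        numeric = numeric.groupby(level=0, sort=False).mean()  # skipna by default
    all_missing = numeric.index[numeric.isna().all(axis=1)]
    if len(all_missing):
        logger.warning("%s: %d gene(s) with all-missing values retained: %s",
                       path, len(all_missing), list(all_missing[:5]))
    return OmicsMatrix(values=numeric, kind=kind)


def write_omics_table(matrix: OmicsMatrix, path, config: PipelineConfig | None = None,
                      seed: int | None = None) -> None:
    write_tsv(matrix.values, path, config=config, seed=seed, index_label="gene")


# ---------------------------------------------------------------------------
# trait tables

def write_trait_table(table: TraitTable, path, config: PipelineConfig | None = None,
                      seed: int | None = None) -> None:
    """Write a TraitTable as TSV with 'trait|reader' columns plus a schema sidecar."""
    flat = table.data.copy()
    flat.columns = [f"{t}|{r}" for t, r in flat.columns]
    write_tsv(flat, path, config=config, seed=seed, index_label="patient")
    schema_rows = []
    for name, spec in table.schema.items():
        schema_rows.append({"trait": name, "kind": spec.kind,
                            "levels": ";".join(map(str, spec.levels)), "units": spec.units})
    write_tsv(pd.DataFrame(schema_rows).set_index("trait"),
              Path(str(path) + ".schema.tsv"), config=config, seed=seed, index_label="trait")


def read_trait_table(path) -> TraitTable:
    flat = read_tsv(path)
    cols = []
    for c in flat.columns:
        if "|" not in c:
            raise ParameterError(f"trait column {c!r} lacks a '|reader' suffix")
        cols.append(tuple(c.split("|", 1)))
    flat.columns = pd.MultiIndex.from_tuples(cols, names=["trait", "reader"])
    schema_df = read_tsv(Path(str(path) + ".schema.tsv"))
    schema = {}
    for name, row in schema_df.iterrows():
        levels = tuple(str(row["levels"]).split(";")) if isinstance(row["levels"], str) and row["levels"] else ()
        schema[str(name)] = TraitSpec(kind=row["kind"], levels=levels,
                                      units=row.get("units", "") if isinstance(row.get("units", ""), str) else "")
    return TraitTable(flat, schema)


# ---------------------------------------------------------------------------
# association reports

def write_association_report(results: Sequence, path, alpha: float,
                             config: PipelineConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Write the alpha-filtered association table; the full table goes alongside.

    The filtered report contains exactly the rows with raw p strictly below
    ``alpha``, sorted by feature then raw p.  The unfiltered table is written
    to ``<path>.full.tsv``.  A duplicated (feature, protein) pair is an error.
    Returns the filtered frame.
    """
    if not (0 < alpha <= 1):
        raise ParameterError(f"alpha must lie in (0, 1], got {alpha}")
    rows = []
    for r in results:
        rows.append({
            "feature": r.feature, "protein": r.protein, "feature_kind": r.feature_kind,
            "statistic": r.statistic, "effect_name": r.effect_name, "effect": r.effect,
            "p_raw": r.p_raw, "p_adjusted": r.p_adjusted, "method": r.method, "n": r.n,
        })
    full = pd.DataFrame(rows, columns=["feature", "protein", "feature_kind", "statistic",
                                       "effect_name", "effect", "p_raw", "p_adjusted",
                                       "method", "n"])
    if not full.empty and full.duplicated(subset=["feature", "protein"]).any():
        dup = full[full.duplicated(subset=["feature", "protein"], keep=False)]
        raise ParameterError(f"duplicated (feature, protein) pairs: "
                             f"{dup[['feature', 'protein']].drop_duplicates().values.tolist()}")
    full = full.sort_values(["feature", "p_raw"], kind="mergesort").reset_index(drop=True)
    filtered = full[full["p_raw"] < alpha].reset_index(drop=True)
    write_tsv(filtered.set_index("feature"), path, config=config, seed=seed, index_label="feature")
    write_tsv(full.set_index("feature"), Path(str(path) + ".full.tsv"),
              config=config, seed=seed, index_label="feature")
    return filtered
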