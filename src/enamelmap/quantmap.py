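"""Volume-normalized spatial abundance maps from filtered peptide records.

Protein abundance follows the top-3 convention of label-free quantification:
the summed chromatographic peak areas of the protein's three most abundant
unique peptides at each location (fewer if fewer were observed).  Abundances
are then normalized for sampled block volume against a reference volume of
2.14 mm^3, and for visualization rescaled per row to percent of the row's
maximum within one tooth crown, or natural-log transformed.

Scales are tracked explicitly on the matrix (``raw_area`` ->
``volume_normalized`` -> ``percent`` / ``natural_log``); operations refuse
inputs on the wrong scale only where the result would be meaningless
(logging a percent scale is allowed, percent-scaling twice is a no-op).

Canonical pipeline order is top3 -> volume_normalize -> {percent | log};
this order is fixed and regression-tested, because volume normalization is a
per-column rescaling and percent scaling a per-row one — they do not commute
with the log transform cell-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

REFERENCE_VOLUME_MM3 = 2.14

SCALES = ("raw_area", "volume_normalized", "percent", "natural_log")


@dataclass
class AbundanceMatrix:
    """Proteins (or peptides) x locations matrix with missingness.

    ``values`` is a DataFrame (rows: protein/peptide ids, columns:
    location_ids) with NaN for missing; ``scale`` tags the current unit.
    ``audit`` accumulates counts of rows/cells dropped or converted by the
    scale operations.
    """

    values: pd.DataFrame
    scale: str = "raw_area"
    audit: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale tag {self.scale!r}")

    @property
    def row_ids(self):
        return list(self.values.index)

    @property
    def col_ids(self):
        return list(self.values.columns)


def top3_abundance(records, grid, n_top=3):
    """Top-``n_top`` unique-peptide abundance per protein x location.

    At each location, areas of the same peptide sequence are pooled (charge
    states and replicate observations sum), the ``n_top`` largest pooled
    unique-peptide areas are summed; ties at the cut are broken by
    lexicographic peptide sequence so the result is deterministic.  Locations
    with no observation are missing.
    """
    locations = [b.location_id for b in grid]
    cells = {}  # (protein, location) -> {sequence: pooled area}
    for r in records:
        if not r.is_unique:
            continue
        pool = cells.setdefault((r.protein_accession, r.location_id), {})
        pool[r.sequence] = pool.get(r.sequence, 0.0) + r.peak_area

    proteins = sorted({p for p, _ in cells})
    out = pd.DataFrame(np.nan, index=proteins, columns=locations)
    for (prot, loc), pool in cells.items():
        ranked = sorted(pool.items(), key=lambda kv: (-kv[1], kv[0]))
        out.at[prot, loc] = sum(a for _, a in ranked[:n_top])
    return AbundanceMatrix(out, "raw_area")


def volume_normalize(matrix, grid, reference_volume=REFERENCE_VOLUME_MM3):
    """Rescale each location by (reference volume / block volume).

    Equal tissue concentrations in blocks of different size then map to equal
    normalized abundances.
    """
    if matrix.scale not in ("raw_area",):
        raise ValidationError(
            f"volume_normalize expects raw_area scale, got {matrix.scale!r}"
        )
    vol = {b.location_id: b.volume_mm3 for b in grid}
    missing = [c for c in matrix.values.columns if c not in vol]
    if missing:
        raise ValidationError(f"no block volume for location(s) {missing}")
    for c in matrix.values.columns:
        if vol[c] <= 0:
            raise ValidationError(f"non-positive volume for {c}: {vol[c]}")
    factors = pd.Series({c: reference_volume / vol[c] for c in matrix.values.columns})
    return AbundanceMatrix(matrix.values.mul(factors, axis=1), "volume_normalized",
                           dict(matrix.audit))


def percent_scale(matrix, grid=None):
    """Rescale each row to percent of its maximum.

    With *grid* supplied, the maximum is taken within each tooth crown and
    each tooth's columns are scaled separately (a row then peaks at 100 in
    every tooth where it was observed); without it the maximum is global.
    Rows that are all-missing, or whose maximum is 0 in every scaled group,
    are dropped and counted in the audit.
    """
    if matrix.scale == "percent":
        return matrix
    vals = matrix.values
    if grid is None:
        groups = {None: list(vals.columns)}
    else:
        groups = {}
        for b in grid:
            if b.location_id in vals.columns:
                groups.setdefault(b.tooth, []).append(b.location_id)

    scaled = pd.DataFrame(np.nan, index=vals.index, columns=vals.columns)
    for cols in groups.values():
        sub = vals[cols]
        rowmax = sub.max(axis=1, skipna=True)
        ok = rowmax > 0
        scaled.loc[ok, cols] = sub.loc[ok].div(rowmax[ok], axis=0) * 100.0

    keep = scaled.notna().any(axis=1)
    audit = dict(matrix.audit)
    audit["percent_rows_dropped"] = int((~keep).sum())
    audit["percent_dropped_ids"] = list(scaled.index[~keep])
    return AbundanceMatrix(scaled.loc[keep], "percent", audit)


def log_transform(matrix):
    """Natural-log transform; zeros become missing (audited), negatives raise."""
    vals = matrix.values
    if (vals < 0).any().any():
        raise ValidationError("log_transform: negative values present")
    zeros = int((vals == 0).sum().sum())
    audit = dict(matrix.audit)
    audit["log_zeros_to_missing"] = zeros
    out = np.log(vals.where(vals > 0))
    return AbundanceMatrix(out, "natural_log", audit)


def summarize_grid(matrix, grid):
    """Per-location total abundance ("amount") and non-missing row count
    ("diversity"), as a DataFrame indexed by location with block metadata."""
    vals = matrix.values
    rows = []
    for b in grid:
        col = vals[b.location_id] if b.location_id in vals.columns else pd.Series(dtype=float)
        rows.append({
            "location": b.location_id, "tooth": b.tooth, "grid_row": b.grid_row,
            "grid_col": b.grid_col, "stage": b.stage,
            "total_amount": float(col.sum(skipna=True)),
            "diversity": int(col.notna().sum()),
        })
    return pd.DataFrame(rows).set_index("location")


def write_matrix(matrix, path):
    """Serialize as TSV (rows x locations); scale recorded in a header comment."""
    with open(path, "w") as fh:
        fh.write(f"# scale={matrix.scale}\n")
        matrix.values.to_csv(fh, sep="\t")


def read_matrix(path):
    """Read a matrix written by :func:`write_matrix`, restoring the scale tag."""
    scale = "raw_area"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# scale="):
            scale = first.strip().split("=", 1)[1]
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return AbundanceMatrix(df, scale)


def write_long(matrix, path):
    """Long-format TSV (row, location, value, scale), missing cells omitted."""
    long = (matrix.values.stack().rename("value").reset_index())
    long.columns = ["row", "location", "value"]
    long["scale"] = matrix.scale
    long.to_csv(path, sep="\t", index=False)


def grid_overlay(matrix, grid, row_id):
    """(tooth, grid_row, grid_col, value) table for one matrix row, for
    plotting spatial maps block by block."""
    vals = matrix.values.loc[row_id]
    rows = [{"tooth": b.tooth, "grid_row": b.grid_row, "grid_col": b.grid_col,
             "value": vals.get(b.location_id, np.nan)} for b in grid]
    return pd.DataFrame(rows)
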