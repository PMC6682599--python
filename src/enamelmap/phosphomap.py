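"""Marker-peptide validation and spatial phospho-occupancy maps.

Four isoform-discriminating marker peptides track site phosphorylation of
the classic enamel matrix proteins across the sample grid: the amelogenin
N-terminal peptides distinguishing the P190 splice product from P173/LRAP
products (both phosphorylated on the serine at parent position 16), an
ameloblastin N-terminal peptide, and the enamelin peptide shared by the
32 kDa cleavage product.  Occupancy at a location is the scale-free ratio
P : (P + NP) of the summed peak area of the phosphorylated form over the
summed area of both forms, so volume normalization cancels and raw
(or volume-normalized) areas give identical maps.

Markers are validated by in-silico tryptic digestion under the search rules
used for identification: cleavage C-terminal to K/R, optionally permitted
before proline, at most two missed cleavages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tables_io import read_fasta

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class MarkerPeptide:
    """An isoform-discriminating peptide with a known phosphosite."""

    marker_id: str
    sequence: str
    phospho_position: int  # 1-based within the peptide
    parent_accession: str
    parent_products: tuple = ()

    def __post_init__(self):
        if not 1 <= self.phospho_position <= len(self.sequence):
            raise ValidationError(
                f"marker {self.marker_id}: phospho position "
                f"{self.phospho_position} outside peptide"
            )
        res = self.sequence[self.phospho_position - 1]
        if res not in "STY":
            raise ValidationError(
                f"marker {self.marker_id}: residue at phospho position is "
                f"{res!r}, expected S/T/Y"
            )


class DigestPeptide(NamedTuple):
    sequence: str
    start: int  # 0-based offset in the parent
    missed_cleavages: int


def builtin_markers():
    """The four bundled marker peptides (amelogenin P190 and P173/LRAP,
    ameloblastin N-terminal, enamelin 32 kDa)."""
    text = resources.files("enamelmap.data").joinpath("markers.json").read_text()
    return [
        MarkerPeptide(
            marker_id=m["marker_id"], sequence=m["sequence"],
            phospho_position=m["phospho_position"],
            parent_accession=m["parent_accession"],
            parent_products=tuple(m.get("parent_products", ())),
        )
        for m in json.loads(text)
    ]


def builtin_parent_sequences():
    """Bundled parent sequences for the built-in markers.

    These are constructed synthetic stand-ins (see
    ``data/synthetic_parents.fasta``) that embed each marker at a
    tryptic-producible position; they are packaged for tests and demos only —
    real analyses should supply the organism's FASTA.
    """
    path = resources.files("enamelmap.data").joinpath("synthetic_parents.fasta")
    with resources.as_file(path) as p:
        return read_fasta(p)


def read_markers(path):
    with open(path) as fh:
        raw = json.load(fh)
    return [MarkerPeptide(m["marker_id"], m["sequence"], m["phospho_position"],
                          m["parent_accession"],
                          tuple(m.get("parent_products", ()))) for m in raw]


# ---------------------------------------------------------------------------
# in-silico digestion


def cleavage_sites(sequence, cleave_before_proline=True):
    """0-based indices i such that the bond after residue i is cleaved:
    C-terminal to K/R; when the proline rule is enforced
    (``cleave_before_proline=False``), K/R followed by P is not a site."""
    bad = set(sequence) - _AA
    if bad:
        raise ValidationError(f"illegal residue(s) in sequence: {sorted(bad)}")
    return [
        i for i in range(len(sequence) - 1)
        if sequence[i] in "KR"
        and (cleave_before_proline or sequence[i + 1] != "P")
    ]


def digest(sequence, max_missed=2, cleave_before_proline=True):
    """Tryptic digest returning every product with 0..``max_missed`` missed
    cleavages as :class:`DigestPeptide` tuples."""
    sites = cleavage_sites(sequence, cleave_before_proline)
    bounds = [0] + [i + 1 for i in sites] + [len(sequence)]
    out = []
    for a in range(len(bounds) - 1):
        for b in range(a + 1, min(a + 2 + max_missed, len(bounds))):
            missed = b - a - 1
            out.append(DigestPeptide(sequence[bounds[a]:bounds[b]],
                                     bounds[a], missed))
    return out


def validate_markers(markers, fasta_map, max_missed=2, cleave_before_proline=True):
    """Check each marker against its parent sequence.

    Confirms the marker is a substring of its parent and is producible by
    tryptic digestion under the given rules, and reports the phosphosite in
    both peptide-internal and parent coordinates.  Failures become report
    rows, not exceptions.  Returns a DataFrame.
    """
    rows = []
    for m in markers:
        row = {
            "marker_id": m.marker_id, "parent": m.parent_accession,
            "found_in_parent": False, "tryptic": False,
            "peptide_phospho_position": m.phospho_position,
            "parent_phospho_position": None, "ok": False, "reason": "",
        }
        parent = fasta_map.get(m.parent_accession)
        if parent is None:
            row["reason"] = f"parent {m.parent_accession!r} absent from FASTA"
            rows.append(row)
            continue
        start = parent.find(m.sequence)
        if start < 0:
            row["reason"] = "marker sequence not found in parent"
            rows.append(row)
            continue
        row["found_in_parent"] = True
        row["parent_phospho_position"] = start + m.phospho_position
        products = {p.sequence for p in digest(parent, max_missed,
                                               cleave_before_proline)}
        row["tryptic"] = m.sequence in products
        if not row["tryptic"]:
            row["reason"] = "marker not producible by digestion under given rules"
        row["ok"] = row["found_in_parent"] and row["tryptic"]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# phospho / non-phospho pairing


@dataclass
class PhosphoPairMap:
    """Per-location phosphorylated (P) and unphosphorylated (NP) marker
    abundances, and after :func:`occupancy_ratio` their P:(P+NP) ratio."""

    marker_id: str
    table: pd.DataFrame  # index: location; columns P_abundance, NP_abundance[, ratio]
    audit: dict = field(default_factory=dict)


def pair_abundances(records, marker, grid=None):
    """Collect P and NP pools for one marker across locations.

    P sums areas of records matching the marker sequence with a Phospho at
    the marker position; NP sums matching records carrying no Phospho at all.
    Records with a Phospho elsewhere in the peptide belong to neither pool
    and are counted in the audit.  Other modifications (oxidation,
    deamidation, ...) are ignored for matching.  Locations with no matching
    record have missing P and NP.
    """
    if grid is not None:
        locations = [b.location_id for b in grid]
    else:
        locations = sorted({r.location_id for r in records})
    p = pd.Series(np.nan, index=locations)
    np_ = pd.Series(np.nan, index=locations)
    other_site = 0
    for r in records:
        if r.sequence != marker.sequence:
            continue
        phospho_positions = {pos for pos, name in r.modifications if name == "Phospho"}
        if marker.phospho_position in phospho_positions:
            p[r.location_id] = (0.0 if np.isnan(p[r.location_id])
                                else p[r.location_id]) + r.peak_area
        elif not phospho_positions:
            np_[r.location_id] = (0.0 if np.isnan(np_[r.location_id])
                                  else np_[r.location_id]) + r.peak_area
        else:
            other_site += 1
    table = pd.DataFrame({"P_abundance": p, "NP_abundance": np_})
    table.index.name = "location"
    return PhosphoPairMap(marker.marker_id, table,
                          {"records_phospho_other_site": other_site})


def occupancy_ratio(pair_map, crown_normalize=False):
    """Add the P:(P+NP) ratio to a pair map.

    A missing pool counts as zero when the other form was observed; the
    ratio is undefined (missing) only where neither form was observed or
    both areas are zero.  With ``crown_normalize`` the per-location ratios
    are additionally divided by the crown-wide pooled ratio (off by default).
    """
    t = pair_map.table.copy()
    p = t["P_abundance"].fillna(0.0)
    np_ = t["NP_abundance"].fillna(0.0)
    total = p + np_
    observed = t["P_abundance"].notna() | t["NP_abundance"].notna()
    ratio = pd.Series(np.nan, index=t.index)
    ok = observed & (total > 0)
    ratio[ok] = p[ok] / total[ok]
    if crown_normalize:
        pooled = p[ok].sum() / total[ok].sum() if total[ok].sum() > 0 else np.nan
        ratio = ratio / pooled
    t["ratio"] = ratio
    return PhosphoPairMap(pair_map.marker_id, t, dict(pair_map.audit))


def write_pair_map(pair_map, path):
    """Long-format TSV export of a pair map."""
    out = pair_map.table.reset_index()
    out.insert(0, "marker_id", pair_map.marker_id)
    out.to_csv(path, sep="\t", index=False)
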