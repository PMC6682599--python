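"""Reading and writing of the pipeline's file formats, plus identification filters.

Formats
-------
Peptide report
    Tab-separated with header ``sequence  modifications  protein  location
    area  significance  unique``.  The ``modifications`` column is a
    semicolon-separated list of ``pos:Name`` entries (1-based position within
    the peptide; one canonical name per modification, e.g. ``Phospho``);
    empty string means unmodified.  ``unique`` is ``1``/``0``.
Grid configuration
    JSON: a list of sample-block objects (``location_id``, ``tooth``,
    ``grid_row``, ``grid_col``, ``volume_mm3``, ``stage``).  Grid coordinates
    are 0-based; row runs cuspal -> cervical, column runs outer enamel
    surface -> DEJ.
FASTA
    Parsed with Biopython; sequences are upper-cased and validated against
    the 20 standard amino acids.

Identification filtering follows the upstream convention for label-free
proteomics reports: a protein is considered identified only if it is backed
by at least two distinct unique peptide sequences (dataset-wide) and its
identification significance (on the -10lgP scale) meets a threshold,
20 by default.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

from .errors import FormatError, ValidationError

STAGE_VOCABULARY = (
    "secretory",
    "early_maturation",
    "late_maturation",
    "erupted",
    "DEJ",
    "dentin",
    "bone",
)

_AA = set("ACDEFGHIKLMNPQRSTVWY")

REPORT_COLUMNS = (
    "sequence",
    "modifications",
    "protein",
    "location",
    "area",
    "significance",
    "unique",
)

_MOD_RE = re.compile(r"^(\d+):([A-Za-z][A-Za-z0-9_-]*)$")


@dataclass(frozen=True)
class SampleBlock:
    """One diced grid location on a sectioned tooth crown."""

    location_id: str
    tooth: str
    grid_row: int
    grid_col: int
    volume_mm3: float
    stage: str

    def __post_init__(self):
        if self.volume_mm3 <= 0:
            raise ValidationError(
                f"block {self.location_id!r}: volume must be > 0 mm^3, "
                f"got {self.volume_mm3}"
            )
        if self.stage not in STAGE_VOCABULARY:
            raise ValidationError(
                f"block {self.location_id!r}: unknown stage {self.stage!r}; "
                f"expected one of {STAGE_VOCABULARY}"
            )


@dataclass(frozen=True)
class PeptideRecord:
    """One quantified peptide observation at one sample location.

    ``modifications`` is a tuple of (1-based position in peptide, name).
    ``significance`` is on the -10lgP scale and is carried per protein as
    produced upstream.  ``is_unique`` flags peptides ascribed to a single
    protein.
    """

    sequence: str
    modifications: tuple = field(default_factory=tuple)
    protein_accession: str = ""
    location_id: str = ""
    peak_area: float = 0.0
    significance: float = 0.0
    is_unique: bool = True

    def __post_init__(self):
        bad = set(self.sequence) - _AA
        if not self.sequence or bad:
            raise ValidationError(
                f"peptide {self.sequence!r}: illegal residues {sorted(bad)}"
            )
        for pos, name in self.modifications:
            if not 1 <= pos <= len(self.sequence):
                raise ValidationError(
                    f"peptide {self.sequence!r}: modification {name!r} at "
                    f"position {pos} outside [1, {len(self.sequence)}]"
                )
        if self.peak_area < 0:
            raise ValidationError(
                f"peptide {self.sequence!r}: negative peak area {self.peak_area}"
            )


def parse_modifications(text: str):
    """Parse a ``pos:Name;pos:Name`` modification string."""
    text = text.strip()
    if not text:
        return ()
    mods = []
    for token in text.split(";"):
        m = _MOD_RE.match(token.strip())
        if m is None:
            raise ValidationError(f"bad modification syntax: {token!r}")
        mods.append((int(m.group(1)), m.group(2)))
    return tuple(mods)


def format_modifications(mods) -> str:
    return ";".join(f"{pos}:{name}" for pos, name in mods)


# ---------------------------------------------------------------------------
# grid configuration


def read_grid(path):
    """Read a JSON grid configuration into a list of SampleBlock."""
    with open(path) as fh:
        raw = json.load(fh)
    if isinstance(raw, dict):
        raw = raw["blocks"]
    blocks = [
        SampleBlock(
            location_id=str(b["location_id"]),
            tooth=str(b["tooth"]),
            grid_row=int(b["grid_row"]),
            grid_col=int(b["grid_col"]),
            volume_mm3=float(b["volume_mm3"]),
            stage=str(b["stage"]),
        )
        for b in raw
    ]
    ids = [b.location_id for b in blocks]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate location_id(s) in grid: {dupes}")
    return blocks


def write_grid(blocks, path, seed=None):
    from . import __version__

    payload = {
        "tool": f"enamelmap {__version__}",
        "seed": seed,
        "blocks": [vars(b) for b in blocks],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# peptide report


def read_peptide_report(path, grid):
    """Read a TSV peptide report, checking every location against *grid*.

    Malformed rows are collected and reported together in a single
    :class:`FormatError` listing offending line numbers.
    """
    known = {b.location_id for b in grid}
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"peptide report missing required columns: {missing}")

    # physical line of the header, counting leading comment lines
    header_line = 1
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_line += 1

    records, problems = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        lineno = header_line + 1 + i
        try:
            if row.location not in known:
                raise ValidationError(
                    f"location {row.location!r} not present in grid"
                )
            records.append(
                PeptideRecord(
                    sequence=row.sequence,
                    modifications=parse_modifications(row.modifications),
                    protein_accession=row.protein,
                    location_id=row.location,
                    peak_area=float(row.area),
                    significance=float(row.significance),
                    is_unique=row.unique.strip() in ("1", "True", "true"),
                )
            )
        except (ValidationError, ValueError) as exc:
            problems.append((lineno, str(exc)))
    if problems:
        shown = "; ".join(f"line {n}: {m}" for n, m in problems[:10])
        raise FormatError(
            f"{len(problems)} malformed row(s) in {path}: {shown}", lines=problems
        )
    return records


def write_peptide_report(records, path, seed=None):
    from . import __version__

    df = pd.DataFrame(
        {
            "sequence": [r.sequence for r in records],
            "modifications": [format_modifications(r.modifications) for r in records],
            "protein": [r.protein_accession for r in records],
            "location": [r.location_id for r in records],
            "area": [repr(r.peak_area) for r in records],
            "significance": [repr(r.significance) for r in records],
            "unique": [int(r.is_unique) for r in records],
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# enamelmap {__version__} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# identification filters


def filter_identifications(records, min_unique_peptides=2, min_significance=20.0):
    """Apply protein-level identification filters.

    A protein's records are retained iff, dataset-wide, it has at least
    ``min_unique_peptides`` distinct unique peptide sequences and its
    significance (max over its records, -10lgP scale) is at least
    ``min_significance``.  Returns ``(retained records, audit DataFrame)``;
    the audit has one row per input protein with peptide counts and the
    applied decision.  Filtering never raises; it only excludes.
    """
    by_protein = {}
    for r in records:
        by_protein.setdefault(r.protein_accession, []).append(r)

    keep, audit_rows = set(), []
    for acc in sorted(by_protein):
        recs = by_protein[acc]
        uniq_seqs = {r.sequence for r in recs if r.is_unique}
        sig = max(r.significance for r in recs)
        retained = len(uniq_seqs) >= min_unique_peptides and sig >= min_significance
        if retained:
            keep.add(acc)
        audit_rows.append(
            {
                "protein": acc,
                "n_records": len(recs),
                "n_unique_peptides": len(uniq_seqs),
                "significance": sig,
                "retained": retained,
            }
        )
    retained_records = [r for r in records if r.protein_accession in keep]
    audit = pd.DataFrame(
        audit_rows,
        columns=["protein", "n_records", "n_unique_peptides", "significance", "retained"],
    )
    return retained_records, audit


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path):
    """Read FASTA into an accession -> upper-case sequence mapping."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if acc in out:
            raise ValidationError(f"duplicate FASTA accession {acc!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - _AA
        if bad:
            raise ValidationError(
                f"FASTA record {acc!r}: illegal residues {sorted(bad)}"
            )
        out[acc] = seq
    return out
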