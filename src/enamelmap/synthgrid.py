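"""Synthetic diced-crown datasets with the statistical structure the analysis assumes.

The generator emulates the study design the pipeline was built for: two molar
crowns sectioned and diced into a grid of sample blocks (20 tooth blocks plus
one alveolar-bone sample, 21 locations in total), each block carrying an
a-priori developmental-stage label (secretory, early/late maturation, erupted,
DEJ-adjacent, dentin, bone).  Protein abundance follows a stage-structured
mean on the natural-log peak-area scale; individual peptides of a protein
respond with a fixed multiplicative offset (ionization efficiency), and
observations carry multiplicative log-normal noise.  Peak areas below a
detection threshold are left-censored (missing), emulating detection-limit
white space in real peptide maps.  Phospho-marker peptides are emitted as a
phosphorylated/unphosphorylated pair whose expected area split equals a
configured per-location occupancy.

Randomness is organised as one global seed with per-protein substreams, so
adding proteins to a configuration does not reshuffle the draws of existing
ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tables_io import STAGE_VOCABULARY, PeptideRecord, SampleBlock

STAGES = STAGE_VOCABULARY

# letters used to build synthetic tryptic peptide bodies (no K/R internally)
_BODY_AA = "ACDEFGHILMNPQSTVWY"

# abundance-profile classes on the natural-log peak-area scale, one mean per
# stage: (secretory, early_maturation, late_maturation, erupted, DEJ, dentin,
# bone).  Magnitudes mirror the dynamic range of label-free peak areas
# (roughly e^10 .. e^16) with stage contrasts of 2-4 log units for the
# stage-specific classes, i.e. one to two orders of magnitude.
PROFILE_CLASSES = {
    "enamel_matrix": (16.0, 15.0, 12.5, 11.5, 13.0, 11.0, 10.5),
    "maturation": (10.5, 14.5, 15.5, 13.5, 12.0, 11.0, 11.0),
    "dej": (11.5, 11.5, 12.0, 12.0, 15.5, 13.5, 12.5),
    "cuspal": (10.5, 11.0, 12.0, 15.5, 11.5, 10.5, 10.5),
    "skeletal": (11.0, 11.0, 11.5, 12.0, 13.5, 15.5, 15.5),
    "background": (12.5, 12.5, 12.5, 12.5, 12.5, 12.5, 12.5),
}

# marker parents are abundant enamel-matrix proteins; their floor stays well
# above the default detection limit so the minor phospho form is observable
_MARKER_PROFILE = (16.0, 15.5, 14.5, 13.5, 14.0, 13.0, 12.5)

# built-in phospho-occupancy templates by stage, in [0.1, 0.9]: amelogenin
# N-terminal products most phosphorylated in secretory/early-maturation
# enamel, ameloblastin the reverse (more phosphorylated in mature enamel),
# enamelin heavily phosphorylated throughout.
_OCCUPANCY_TEMPLATES = {
    "P190": {
        "secretory": 0.80, "early_maturation": 0.70, "late_maturation": 0.45,
        "erupted": 0.35, "DEJ": 0.50, "dentin": 0.30, "bone": 0.30,
    },
    "P173_LRAP": {
        "secretory": 0.85, "early_maturation": 0.75, "late_maturation": 0.50,
        "erupted": 0.40, "DEJ": 0.55, "dentin": 0.35, "bone": 0.30,
    },
    "AMBN_N": {
        "secretory": 0.20, "early_maturation": 0.35, "late_maturation": 0.70,
        "erupted": 0.80, "DEJ": 0.60, "dentin": 0.50, "bone": 0.45,
    },
    "ENAM_32k": {
        "secretory": 0.85, "early_maturation": 0.90, "late_maturation": 0.90,
        "erupted": 0.90, "DEJ": 0.85, "dentin": 0.80, "bone": 0.75,
    },
}

# marker_id -> (sequence, 1-based phospho position, synthetic parent accession)
MARKER_DEFS = {
    "P190": ("LPPHPGHPGYINFSYEK", 14, "AMELX_P190_SYN"),
    "P173_LRAP": ("MPLPPHPGHPGYINFSYEVLTPLK", 16, "AMELX_P173_SYN"),
    "AMBN_N": ("QPGTPGVASLSLETMR", 11, "AMBN_SYN"),
    "ENAM_32k": ("GYHGFGGRPPYYSEEMFEQDFEKPK", 13, "ENAM_SYN"),
}


def default_stage_layout():
    """The default 21-location layout: two teeth (M3 unerupted, M2 partially
    erupted), 20 tooth blocks plus one alveolar-bone sample.  Rows run
    cuspal -> cervical, columns run outer surface -> DEJ."""
    m3 = [
        ("M3_r0c0", "M3", 0, 0, "late_maturation"),
        ("M3_r0c1", "M3", 0, 1, "late_maturation"),
        ("M3_r0c2", "M3", 0, 2, "DEJ"),
        ("M3_r1c0", "M3", 1, 0, "early_maturation"),
        ("M3_r1c1", "M3", 1, 1, "early_maturation"),
        ("M3_r1c2", "M3", 1, 2, "DEJ"),
        ("M3_r2c0", "M3", 2, 0, "secretory"),
        ("M3_r2c1", "M3", 2, 1, "secretory"),
        ("M3_r2c2", "M3", 2, 2, "DEJ"),
        ("M3_r3c0", "M3", 3, 0, "secretory"),
        ("M3_r3c1", "M3", 3, 1, "secretory"),
        ("M3_r3c2", "M3", 3, 2, "dentin"),
    ]
    m2 = [
        ("M2_r0c0", "M2", 0, 0, "erupted"),
        ("M2_r0c1", "M2", 0, 1, "erupted"),
        ("M2_r0c2", "M2", 0, 2, "DEJ"),
        ("M2_r1c0", "M2", 1, 0, "erupted"),
        ("M2_r1c1", "M2", 1, 1, "late_maturation"),
        ("M2_r1c2", "M2", 1, 2, "DEJ"),
        ("M2_r2c0", "M2", 2, 0, "late_maturation"),
        ("M2_r2c1", "M2", 2, 1, "dentin"),
    ]
    bone = [("BONE_1", "BONE", 0, 0, "bone")]
    return m3 + m2 + bone


@dataclass
class SimulationConfig:
    """Parameters of one synthetic diced-crown experiment.

    ``stage_effect_matrix`` is a proteins x stages DataFrame of mean
    log-abundances; when ``None`` a planted-structure default is built from
    ``n_proteins`` and ``seed`` (six abundance-profile classes in rotation,
    marker parents appended).  ``phospho_profiles`` maps marker_id ->
    {location_id: true occupancy in [0, 1]}; ``None`` selects the built-in
    stage-based templates for all four markers.
    """

    n_locations: int = 21
    stage_layout: list = field(default_factory=default_stage_layout)
    n_proteins: int = 60
    n_peptides_per_protein: tuple = (3, 8)
    stage_effect_matrix: pd.DataFrame | None = None
    peptide_response_sd: float = 0.5
    noise_sd: float = 0.3
    detection_threshold: float = math.exp(10.0)
    volume_mean: float = 2.3
    volume_sd: float = 0.4
    phospho_profiles: dict | None = None
    seed: int = 0

    def validate(self):
        if self.n_locations <= 0 or self.n_proteins <= 0:
            raise ValidationError("n_locations and n_proteins must be positive")
        if len(self.stage_layout) != self.n_locations:
            raise ValidationError(
                f"stage_layout has {len(self.stage_layout)} entries, "
                f"expected n_locations={self.n_locations}"
            )
        lo, hi = self.n_peptides_per_protein
        if not (0 < lo <= hi):
            raise ValidationError("n_peptides_per_protein range must be 1 <= lo <= hi")
        for name, v in (("peptide_response_sd", self.peptide_response_sd),
                        ("noise_sd", self.noise_sd)):
            if v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")
        if self.detection_threshold < 0:
            raise ValidationError("detection_threshold must be >= 0")
        if self.volume_mean <= 0 or self.volume_sd < 0:
            raise ValidationError("volume_mean must be > 0 and volume_sd >= 0")
        for _, _, _, _, stage in self.stage_layout:
            if stage not in STAGES:
                raise ValidationError(
                    f"unknown stage label {stage!r}; expected one of {STAGES}"
                )
        for marker, prof in (self.phospho_profiles or {}).items():
            for loc, occ in prof.items():
                if not 0.0 <= occ <= 1.0:
                    raise ValidationError(
                        f"occupancy for {marker} at {loc} outside [0, 1]: {occ}"
                    )


def _encode_index(i, width):
    """Map an integer to a fixed-width string over the peptide-body alphabet."""
    base = len(_BODY_AA)
    out = []
    for _ in range(width):
        out.append(_BODY_AA[i % base])
        i //= base
    return "".join(reversed(out))


def _protein_rng(seed, index):
    return np.random.default_rng([int(seed) % (2**31), int(index)])


def default_stage_effects(n_proteins, seed):
    """Planted stage-effect matrix: the six profile classes in rotation with
    a small per-protein baseline jitter (±0.5 log units)."""
    classes = list(PROFILE_CLASSES)
    rows, names, labels = [], [], []
    for i in range(n_proteins):
        cls = classes[i % len(classes)]
        jitter = _protein_rng(seed, i).uniform(-0.5, 0.5)
        rows.append(np.asarray(PROFILE_CLASSES[cls], dtype=float) + jitter)
        names.append(f"PROT{i:04d}_{cls.upper()}")
        labels.append(cls)
    mat = pd.DataFrame(rows, index=names, columns=list(STAGES))
    mat.attrs["class_labels"] = dict(zip(names, labels))
    return mat


def default_phospho_profiles(stage_layout):
    """Per-location occupancy for the four built-in markers, from the
    stage-based templates."""
    return {
        marker: {loc: _OCCUPANCY_TEMPLATES[marker][stage]
                 for loc, _, _, _, stage in stage_layout}
        for marker in MARKER_DEFS
    }


def _resolve(config):
    config.validate()
    effects = config.stage_effect_matrix
    if effects is None:
        effects = default_stage_effects(config.n_proteins, config.seed)
    profiles = config.phospho_profiles
    if profiles is None:
        profiles = default_phospho_profiles(config.stage_layout)
    for marker in profiles:
        if marker not in MARKER_DEFS:
            raise ValidationError(f"unknown marker id {marker!r}")
    return effects, profiles


def simulate_dataset(config: SimulationConfig):
    """Simulate one diced-crown dataset.

    Returns ``(grid, peptides, truth)`` where *grid* is a list of
    :class:`SampleBlock`, *peptides* a list of :class:`PeptideRecord` and
    *truth* a dict of ground-truth DataFrames (``proteins``, ``peptides``,
    ``occupancy``, ``annotations``).  Identical config and seed give
    identical output.
    """
    effects, profiles = _resolve(config)

    # sample-block geometry: volumes from one dedicated substream
    vol_rng = _protein_rng(config.seed, 2_000_000_011)
    grid = []
    for loc, tooth, row, col, stage in config.stage_layout:
        vol = float(np.clip(vol_rng.normal(config.volume_mean, config.volume_sd),
                            0.2, None))
        grid.append(SampleBlock(loc, tooth, row, col, vol, stage))
    stage_of = {b.location_id: b.stage for b in grid}
    locations = [b.location_id for b in grid]

    class_labels = effects.attrs.get("class_labels", {})
    lo, hi = config.n_peptides_per_protein
    records = []
    protein_truth, peptide_truth = [], []

    def emit_protein(acc, idx, mu_row, n_peps, rng, sig):
        offsets = rng.normal(0.0, config.peptide_response_sd, size=n_peps)
        for j in range(n_peps):
            body_len = int(rng.integers(6, 13))
            body = "".join(_BODY_AA[k] for k in rng.integers(0, len(_BODY_AA),
                                                             size=body_len))
            seq = _encode_index(idx, 3) + _encode_index(j, 2) + body + "K"
            peptide_truth.append({"protein": acc, "peptide": seq,
                                  "response_offset": offsets[j]})
            for loc in locations:
                mu = mu_row[stage_of[loc]] + offsets[j]
                area = math.exp(mu + rng.normal(0.0, config.noise_sd)
                                if config.noise_sd > 0 else mu)
                if area < config.detection_threshold:
                    continue  # left-censored: below detection limit
                records.append(PeptideRecord(
                    sequence=seq, modifications=(), protein_accession=acc,
                    location_id=loc, peak_area=area, significance=sig,
                    is_unique=True))
        protein_truth.append({"protein": acc,
                              "class": class_labels.get(acc, "custom"),
                              **{s: float(mu_row[s]) for s in STAGES}})

    for i, acc in enumerate(effects.index):
        rng = _protein_rng(config.seed, i)
        sig = float(rng.uniform(30.0, 400.0))
        n_peps = int(rng.integers(lo, hi + 1))
        emit_protein(acc, i, effects.loc[acc], n_peps, rng, sig)

    # marker parents: abundant enamel-matrix proteins carrying the phospho
    # marker peptide pair in addition to ordinary backbone peptides
    occupancy_truth = []
    marker_mu = pd.Series(_MARKER_PROFILE, index=list(STAGES))
    for m, marker in enumerate(sorted(profiles)):
        seq, pos, parent = MARKER_DEFS[marker]
        idx = 1_000_000 + m
        rng = _protein_rng(config.seed, idx)
        sig = float(rng.uniform(200.0, 400.0))
        emit_protein(parent, idx, marker_mu, 3, rng, sig)
        for loc in locations:
            occ = float(profiles[marker][loc])
            total_mu = marker_mu[stage_of[loc]]
            eps_p, eps_np = (rng.normal(0.0, config.noise_sd, size=2)
                             if config.noise_sd > 0 else (0.0, 0.0))
            p_area = occ * math.exp(total_mu + eps_p)
            np_area = (1.0 - occ) * math.exp(total_mu + eps_np)
            occupancy_truth.append({"marker": marker, "location": loc,
                                    "occupancy": occ})
            if p_area >= config.detection_threshold:
                records.append(PeptideRecord(
                    sequence=seq, modifications=((pos, "Phospho"),),
                    protein_accession=parent, location_id=loc,
                    peak_area=p_area, significance=sig, is_unique=True))
            if np_area >= config.detection_threshold:
                records.append(PeptideRecord(
                    sequence=seq, modifications=(), protein_accession=parent,
                    location_id=loc, peak_area=np_area, significance=sig,
                    is_unique=True))

    # annotation table for over-representation tests: the planted class is a
    # term, plus broad terms shared across classes
    ann_rows = []
    for row in protein_truth:
        ann_rows.append({"protein": row["protein"], "term": f"class:{row['class']}"})
        ann_rows.append({"protein": row["protein"], "term": "term:phosphoprotein"})

    truth = {
        "proteins": pd.DataFrame(protein_truth),
        "peptides": pd.DataFrame(peptide_truth),
        "occupancy": pd.DataFrame(occupancy_truth),
        "annotations": pd.DataFrame(ann_rows),
    }
    return grid, records, truth
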