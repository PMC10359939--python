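"""Seeded generators for benchmark bioactivity libraries and imaging screens.

Everything downstream of database extraction can be exercised without any
download: the library generator emits compounds, targets, a bioactivity
table, fingerprints and an availability map with planted structure, and
the screen generator emits 384-well-style plates whose survival fractions
follow the two-component Gaussian mixture the hit-calling model assumes,
together with ground-truth hit labels.

Redundancy in the library benchmark is literal: the members of a planted
cluster share one target set and identical activity records (as truly
redundant probe pairs such as anthracycline analogues do), and their
fingerprints share enough bits to sit at pairwise similarity s*.
Non-redundant compounds occupy compound-specific potency bands, so their
pairwise activity distributions are essentially disjoint.  Fingerprints
are constructed by controlled bit overlap (a global core shared by all
compounds, a per-cluster core, and per-compound unique bits) rather than
from chemistry, so similarity machinery is testable with no SMILES at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem_space import Fingerprint, FingerprintSet
from .core_io import (ASSAY_TYPES, BioactivityTable, CompoundRecord,
                      ScreenPlateSet, TargetRecord, ValidationError)


@dataclass
class SynthLibraryConfig:
    """Knobs for the planted-redundancy bioactivity benchmark.

    Potencies are log10 nM: the default band centre 2.0 ± 1.2 spans roughly
    1 nM .. 100 uM across compounds, with a tight 0.02 within-compound band
    so distinct compounds have well-separated activity profiles.
    """

    n_targets: int = 40
    n_compounds: int = 600
    targets_per_compound: tuple[int, int] = (3, 6)
    log10_potency_mean: float = 2.0
    log10_potency_sd: float = 1.2
    log10_band_sd: float = 0.02
    redundancy_cutoff: float = 0.70  # planted s*
    n_redundant_clusters: int = 20
    cluster_size: int = 10
    bits_per_compound: int = 40
    global_core_bits: int = 6
    fingerprint_nbits: int = 0  # 0 → smallest collision-free size
    availability_rate: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_targets, self.n_compounds, self.n_redundant_clusters,
               self.cluster_size, self.bits_per_compound) <= 0:
            raise ValidationError("all counts must be positive")
        if not (0 < self.redundancy_cutoff < 1):
            raise ValidationError("redundancy_cutoff must be in (0, 1)")
        if not (0 <= self.availability_rate <= 1):
            raise ValidationError("availability_rate must be in [0, 1]")
        if self.n_redundant_clusters * self.cluster_size > self.n_compounds:
            raise ValidationError("clusters do not fit into n_compounds")
        cross = self.global_core_bits / self.bits_per_compound
        if cross >= self.redundancy_cutoff - 0.1:
            raise ValidationError(
                f"infeasible similarity constraints: cross-cluster similarity "
                f"{cross:.2f} must stay below s* - 0.1 = "
                f"{self.redundancy_cutoff - 0.1:.2f}")
        if self.targets_per_compound[0] < 3:
            raise ValidationError(
                "need >= 3 activities per compound (K-S degenerates below)")


@dataclass
class SyntheticLibrary:
    """Generator output plus ground truth (planted cluster membership)."""

    compounds: list[CompoundRecord]
    targets: list[TargetRecord]
    bioactivity: BioactivityTable
    fingerprints: FingerprintSet
    availability: dict[str, bool]
    clusters: list[list[str]]
    config: SynthLibraryConfig


def synth_bioactivity(config: SynthLibraryConfig) -> SyntheticLibrary:
    """Generate a planted-redundancy bioactivity benchmark (pure in seed)."""
    rng = np.random.default_rng(config.seed)
    k = config.bits_per_compound
    g = config.global_core_bits
    core = math.ceil(config.redundancy_cutoff * k)  # within-cluster overlap

    compound_ids = [f"CPD{i:05d}" for i in range(config.n_compounds)]
    target_ids = [f"TGT{i:04d}" for i in range(config.n_targets)]
    targets = [TargetRecord(t, is_cancer_associated=True) for t in target_ids]

    n_clustered = config.n_redundant_clusters * config.cluster_size
    member_ids = rng.choice(config.n_compounds, size=n_clustered, replace=False)
    clusters = [sorted(compound_ids[i] for i in
                       member_ids[j * config.cluster_size:(j + 1) * config.cluster_size])
                for j in range(config.n_redundant_clusters)]
    cluster_of = {cid: j for j, members in enumerate(clusters) for cid in members}

    # --- fingerprints: global core + cluster core + unique block ------------
    n_needed = (g + config.n_redundant_clusters * (core - g)
                + n_clustered * (k - core)
                + (config.n_compounds - n_clustered) * (k - g))
    nbits = config.fingerprint_nbits or 1 << max(10, n_needed.bit_length())
    if nbits < n_needed:
        raise ValidationError(
            f"fingerprint_nbits={nbits} too small; need >= {n_needed} "
            f"for collision-free construction")
    counter = g
    cluster_core_bits = []
    for _ in range(config.n_redundant_clusters):
        cluster_core_bits.append(range(counter, counter + core - g))
        counter += core - g
    fps = FingerprintSet()
    for cid in compound_ids:
        j = cluster_of.get(cid)
        bits = set(range(g))
        if j is not None:
            bits.update(cluster_core_bits[j])
        n_unique = k - len(bits)
        bits.update(range(counter, counter + n_unique))
        counter += n_unique
        for kind in ("ECFP4", "ECFP6"):
            fps.add(cid, Fingerprint(kind, frozenset(bits), nbits))

    # --- activities: identical records within a cluster ---------------------
    lo, hi = config.targets_per_compound
    rows: list[tuple[str, str, str, float]] = []

    def _draw_profile():
        n_t = int(rng.integers(lo, hi + 1))
        tgts = rng.choice(config.n_targets, size=n_t, replace=False)
        center = rng.normal(config.log10_potency_mean, config.log10_potency_sd)
        vals = 10.0 ** (center + rng.normal(0, config.log10_band_sd, size=n_t))
        assays = rng.choice(len(ASSAY_TYPES), size=n_t)
        return [(target_ids[t], ASSAY_TYPES[a], float(v))
                for t, a, v in zip(tgts, assays, vals)]

    cluster_profiles = [_draw_profile() for _ in clusters]
    for cid in compound_ids:
        j = cluster_of.get(cid)
        profile = cluster_profiles[j] if j is not None else _draw_profile()
        rows.extend((cid, t, a, v) for t, a, v in profile)
    table = BioactivityTable(
        pd.DataFrame(rows, columns=["compound_id", "target_id",
                                    "assay_type", "value_nM"]))

    availability = {cid: bool(rng.random() < config.availability_rate)
                    for cid in compound_ids}
    compounds = [CompoundRecord(cid, available=availability[cid])
                 for cid in compound_ids]
    return SyntheticLibrary(compounds=compounds, targets=targets,
                            bioactivity=table, fingerprints=fps,
                            availability=availability, clusters=clusters,
                            config=config)


# ---------------------------------------------------------------------------
# Imaging-screen generator
# ---------------------------------------------------------------------------

@dataclass
class SynthScreenConfig:
    """Knobs for the synthetic imaging screen.

    Defaults mirror the pilot-screen geometry: 6 patient lines, four
    half-log-ish doses 3..3000 nM, a background SF component N(1, 0.05) and
    an active component N(0.3, 0.1) holding 10% of compounds, DMSO nuclei
    counts Poisson around 1000.  Planted hits are active at every dose with
    a mild dose-monotone scaling of the active mean.
    """

    n_patients: int = 6
    n_compounds: int = 325
    concentrations_nM: tuple[float, ...] = (3.0, 30.0, 300.0, 3000.0)
    background_mean: float = 1.0
    background_sd: float = 0.05
    active_fraction: float = 0.1
    active_mean: float = 0.3
    active_sd: float = 0.1
    n_dmso_wells: int = 16
    n_positive_wells: int = 8
    dmso_count_mean: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.active_fraction < 1):
            raise ValidationError("active_fraction must be in [0, 1)")
        if self.dmso_count_mean <= 0:
            raise ValidationError("dmso_count_mean must be positive")
        if len(self.concentrations_nM) < 2:
            raise ValidationError("need >= 2 concentrations")


@dataclass
class SyntheticScreen:
    plates: ScreenPlateSet
    hit_compounds: set[str]
    config: SynthScreenConfig


def synth_screen(config: SynthScreenConfig) -> SyntheticScreen:
    """Generate plate tables with planted strong hits (pure in seed).

    One plate per (patient, concentration); DMSO counts are Poisson, treated
    counts are round(dmso_count_mean * SF) with SF drawn from the background
    or active Gaussian (clipped at 0).  The active mean scales from 1.15x at
    the lowest dose to 0.85x at the highest (mild dose monotonicity).
    """
    rng = np.random.default_rng(config.seed)
    compounds = [f"SCR{i:04d}" for i in range(config.n_compounds)]
    n_hits = int(round(config.active_fraction * config.n_compounds))
    hits = set(rng.choice(compounds, size=n_hits, replace=False)) if n_hits else set()
    conc = list(config.concentrations_nM)
    scales = np.linspace(1.15, 0.85, num=len(conc))

    rows = []
    for p in range(config.n_patients):
        patient = f"P{p + 1}"
        for ci, c in enumerate(conc):
            plate = f"{patient}-D{ci + 1}"
            well = 0
            for _ in range(config.n_dmso_wells):
                well += 1
                rows.append((plate, patient, f"W{well:03d}", "dmso",
                             "", np.nan, int(rng.poisson(config.dmso_count_mean))))
            for _ in range(config.n_positive_wells):
                well += 1
                rows.append((plate, patient, f"W{well:03d}", "positive_control",
                             "STAUROSPORINE", 1000.0,
                             int(rng.poisson(0.02 * config.dmso_count_mean))))
            for cid in compounds:
                well += 1
                if cid in hits:
                    sf = rng.normal(config.active_mean * scales[ci],
                                    config.active_sd)
                else:
                    sf = rng.normal(config.background_mean, config.background_sd)
                count = int(round(config.dmso_count_mean * max(sf, 0.0)))
                rows.append((plate, patient, f"W{well:03d}", "treated",
                             cid, float(c), count))
    df = pd.DataFrame(rows, columns=["plate_id", "patient_id", "well", "role",
                                     "compound_id", "concentration_nM",
                                     "nuclei_count"])
    return SyntheticScreen(plates=ScreenPlateSet(df),
                           hit_compounds=hits, config=config)


def write_truth_labels(screen: SyntheticScreen, path) -> None:
    """Write ground-truth hit labels as a sidecar TSV."""
    ids = sorted({r for r in screen.plates.df.loc[
        screen.plates.df["role"] == "treated", "compound_id"]})
    pd.DataFrame({"compound_id": ids,
                  "is_hit": [c in screen.hit_compounds for c in ids]}
                 ).to_csv(path, sep="\t", index=False)
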