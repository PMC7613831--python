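"""Synthetic multi-omic study generator with recorded ground truth.

Every input the analysis pipeline consumes can be generated here: two
three-group (healthy / SHAM / DMT) RNA-seq count studies with a planted
treatment-induced fatty-acid-oxidation (FAO) module and a disease-induced
fibrosis module; a 14-cell-type tubular epithelial abundance atlas with
proximal-tubule-planted genes; drug and PPAR-isotype target networks with
fenofibrate/PPARalpha dominance; a urinary 1H-NMR cohort with planted
clearance, TCA-cycle and nicotinamide metabolite families, glucose
interference, baseline drift and per-sample dilution factors; and per-animal
morphometry tables with group shifts.

Counts follow a negative-binomial model with shared per-gene dispersion and
log-uniform library sizes -- the same family the differential-expression
engine assumes, so parameter recovery is a fair test. NMR peaks are Gaussian
by default (Lorentzian optional). Physical measurements are drawn from
normals truncated at zero. All generators are deterministic given the seed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .de import CountMatrix
from .deconv import AtlasMatrix, CELL_TYPES, DRUGS, PPAR_ISOTYPES, PT_TYPES, DrugTargetNetwork
from .nmr import Spectrum

GROUPS = ("healthy", "SHAM", "DMT")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ModuleSpec:
    """A planted gene module: member ids plus a log2 effect for its contrast."""

    genes: tuple[str, ...]
    log2_effect: float


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(1, n + 1)]


def default_fao_genes(n_genes: int = 2000, size: int = 40) -> tuple[str, ...]:
    return tuple(_gene_ids(n_genes)[:size])


def default_fibrosis_genes(n_genes: int = 2000, size: int = 40) -> tuple[str, ...]:
    return tuple(_gene_ids(n_genes)[size: 2 * size])


@dataclass
class DrugNetworkSpec:
    """Target-set sizes and overlap structure for drugs and PPAR isotypes."""

    sizes: dict[str, int] = field(
        default_factory=lambda: {
            "fenofibrate": 300, "liraglutide": 80, "metformin": 80,
            "ramipril": 80, "rosuvastatin": 80,
            "PPARA": 250, "PPARD": 100, "PPARG": 100,
        }
    )
    #: fraction of each non-focal set shared with a common background pool
    overlap_fraction: float = 0.1
    #: exact |fenofibrate ∩ PPARA| (None -> max feasible given planted genes)
    feno_ppara_overlap: int | None = 200


@dataclass
class NMRSpec:
    """Planted peak layout and group effects for the urinary cohort."""

    ppm_min: float = 0.2
    ppm_max: float = 10.0
    n_points: int = 12000
    peak_sigma: float = 0.005  # ppm; Gaussian SD of each resonance
    lorentzian: bool = False
    noise_sd: float = 0.05
    baseline_amplitude: float = 1.5
    amplitude_range: tuple[float, float] = (8.0, 20.0)
    dilution_range: tuple[float, float] = (0.5, 2.0)
    n_background: int = 80
    #: per-sample multiplicative biological scatter (lognormal sigma) per peak
    biological_cv: float = 0.025
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "healthy": 8, "untreated_mild": 7, "untreated_severe": 7, "DMT": 8
        }
    )
    #: planted resonances per metabolite family
    family_ppm: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "clearance": (7.84, 7.64, 7.28, 7.05, 2.30, 1.06),
            "tca": (6.52, 5.70, 3.01, 2.45),
            "nicotinamide": (9.28, 8.90, 8.18, 4.48),
            "glucose": (5.24, 3.90, 3.72, 3.54, 3.40, 3.24),
        }
    )
    #: multiplicative group effect per family (clearance falls with disease,
    #: TCA intermediates rise with disease, nicotinamide rises after DMT,
    #: glycosuria dominates the untreated severe phenotype)
    family_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "clearance": {"healthy": 1.0, "untreated_mild": 0.6,
                          "untreated_severe": 0.35, "DMT": 0.9, "SHAM": 0.35},
            "tca": {"healthy": 1.0, "untreated_mild": 1.6,
                    "untreated_severe": 2.6, "DMT": 1.1, "SHAM": 2.6},
            "nicotinamide": {"healthy": 1.0, "untreated_mild": 1.0,
                             "untreated_severe": 1.0, "DMT": 2.2, "SHAM": 1.0},
            "glucose": {"healthy": 0.2, "untreated_mild": 2.0,
                        "untreated_severe": 6.0, "DMT": 0.5, "SHAM": 6.0},
            "background": {"healthy": 1.0, "untreated_mild": 1.0,
                           "untreated_severe": 1.0, "DMT": 1.0, "SHAM": 1.0},
        }
    )


@dataclass
class MorphometrySpec:
    """Group-shifted truncated-normal parameters per measurement.

    means[parameter][group], sd[parameter]. Units: glomerular area um^2,
    PFPF per 8 um GBM, GBM thickness nm, mitochondrial area um^2 and major
    axis um. The treatment shift on mitochondrial geometry makes roundness
    recover toward (and past) healthy values after DMT.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"healthy": 8, "SHAM": 8, "DMT": 8}
    )
    means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "glomerular_area": {"healthy": 7000.0, "SHAM": 9600.0, "DMT": 8000.0},
            "pfpf": {"healthy": 16.0, "SHAM": 10.0, "DMT": 14.0},
            "gbm_thickness": {"healthy": 180.0, "SHAM": 260.0, "DMT": 205.0},
            "mito_area": {"healthy": 0.40, "SHAM": 0.38, "DMT": 0.42},
            "mito_major": {"healthy": 1.15, "SHAM": 1.30, "DMT": 1.05},
        }
    )
    sds: dict[str, float] = field(
        default_factory=lambda: {
            "glomerular_area": 700.0, "pfpf": 1.2, "gbm_thickness": 18.0,
            "mito_area": 0.03, "mito_major": 0.05,
        }
    )


@dataclass
class SyntheticStudyConfig:
    """Everything the generators need, with the study defaults."""

    seed: int = 0
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"healthy": 6, "SHAM": 6, "DMT": 6}
    )
    n_genes: int = 2000
    fao_module: ModuleSpec = None  # type: ignore[assignment]
    fibrosis_module: ModuleSpec = None  # type: ignore[assignment]
    dispersion: float = 0.05
    library_size_range: tuple[float, float] = (0.7, 1.4)
    base_mean_log_mu: float = 4.0
    base_mean_log_sd: float = 1.0
    atlas_fraction: float = 0.6
    drug_specs: DrugNetworkSpec = field(default_factory=DrugNetworkSpec)
    nmr_specs: NMRSpec = field(default_factory=NMRSpec)
    morphometry: MorphometrySpec = field(default_factory=MorphometrySpec)

    def __post_init__(self) -> None:
        if self.fao_module is None:
            self.fao_module = ModuleSpec(default_fao_genes(self.n_genes), 1.5)
        if self.fibrosis_module is None:
            self.fibrosis_module = ModuleSpec(default_fibrosis_genes(self.n_genes), 1.5)
        if self.n_genes <= 0 or any(n <= 0 for n in self.n_per_group.values()):
            raise ValueError("sizes must be positive")
        if set(self.fao_module.genes) & set(self.fibrosis_module.genes):
            raise ValueError("planted modules must be disjoint")
        if not np.isfinite([self.fao_module.log2_effect, self.fibrosis_module.log2_effect]).all():
            raise ValueError("module effects must be finite")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        lo, hi = self.library_size_range
        if lo <= 0 or hi <= 0:
            raise ValueError("library size factors must be positive")
        lo, hi = self.nmr_specs.dilution_range
        if lo <= 0 or hi <= 0:
            raise ValueError("dilution factors must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return _gene_ids(self.n_genes)


@dataclass
class PlantedTruth:
    """Ground-truth record accompanying each generated artifact."""

    true_log2fc: dict[str, dict[str, float]] | None = None
    celltype: dict[str, str] | None = None
    responsiveness: dict[str, list[str]] | None = None
    peak_families: dict[str, str] | None = None  # "ppm" string -> family
    family_group_means: dict[str, dict[str, float]] | None = None
    dilution: dict[str, float] | None = None
    group_means: dict[str, dict[str, float]] | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({k: v for k, v in asdict(self).items() if v is not None},
                      fh, indent=1)


def _rng(config: SyntheticStudyConfig, label: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(label.encode()) % 2**31])
    )


# ---------------------------------------------------------------------------
# RNA-seq count studies


def generate_count_study(
    config: SyntheticStudyConfig, model_label: str
) -> tuple[CountMatrix, PlantedTruth]:
    """Negative-binomial counts for one rat model with planted modules.

    Group means: the fibrosis module is elevated in SHAM (disease effect,
    reverted by treatment, hence "corrected"); the FAO module is induced in
    DMT relative to SHAM. Counts K_ij ~ NB(mean s_j * q_i(group), alpha).
    """
    rng = _rng(config, f"counts:{model_label}")
    genes = config.gene_ids
    n_genes = config.n_genes
    base = np.exp(rng.normal(config.base_mean_log_mu, config.base_mean_log_sd, n_genes))

    fao = np.isin(genes, config.fao_module.genes)
    fib = np.isin(genes, config.fibrosis_module.genes)
    e_fao, e_fib = config.fao_module.log2_effect, config.fibrosis_module.log2_effect
    mult = {
        "healthy": np.ones(n_genes),
        "SHAM": np.where(fib, 2.0**e_fib, 1.0),
        "DMT": np.where(fao, 2.0**e_fao, 1.0),
    }

    cols, sample_ids, group_of = [], [], []
    lo, hi = config.library_size_range
    alpha = config.dispersion
    for group in GROUPS:
        for i in range(config.n_per_group[group]):
            sid = f"{model_label}_{group}_{i + 1}"
            s = np.exp(rng.uniform(np.log(lo), np.log(hi)))
            mean = s * base * mult[group]
            r = 1.0 / alpha
            counts = rng.negative_binomial(r, r / (r + mean))
            cols.append(counts)
            sample_ids.append(sid)
            group_of.append(group)

    counts_df = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(genes, name="gene"), columns=sample_ids
    )
    meta = pd.DataFrame(
        {"group": group_of, "model": model_label},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = PlantedTruth(
        true_log2fc={
            "DMT_vs_SHAM": {
                g: (e_fao if f else (-e_fib if b else 0.0))
                for g, f, b in zip(genes, fao, fib)
            },
            "SHAM_vs_healthy": {
                g: (e_fib if b else 0.0) for g, b in zip(genes, fib)
            },
        }
    )
    return CountMatrix(counts_df, meta), truth


# ---------------------------------------------------------------------------
# cell-type atlas


def generate_atlas(config: SyntheticStudyConfig) -> tuple[AtlasMatrix, PlantedTruth]:
    """Tubular cell-type abundance atlas with the FAO module planted in S1-S3.

    A configurable fraction of the gene universe appears in the atlas; every
    planted FAO gene is present with its maximal abundance in a proximal
    tubule segment (biassed toward S2/S3, the high-peroxisome segments);
    other features get a random true cell type whose abundance is boosted to
    a strict maximum.
    """
    rng = _rng(config, "atlas")
    genes = np.array(config.gene_ids)
    fao = set(config.fao_module.genes)
    others = [g for g in genes if g not in fao]
    n_other = int(round(config.atlas_fraction * config.n_genes)) - len(fao)
    chosen = list(fao) + list(rng.choice(others, size=max(n_other, 0), replace=False))
    chosen = sorted(chosen)

    pt_choices = np.array(["S1", "S2", "S3"])
    abundance = np.exp(rng.normal(1.0, 0.8, size=(len(chosen), len(CELL_TYPES))))
    truth_ct: dict[str, str] = {}
    for i, g in enumerate(chosen):
        if g in fao:
            ct = rng.choice(pt_choices, p=[0.2, 0.4, 0.4])
        else:
            ct = rng.choice([c for c in CELL_TYPES if c not in PT_TYPES])
        j = CELL_TYPES.index(ct)
        abundance[i, j] = abundance[i].max() * 1.5 + 1.0
        truth_ct[g] = str(ct)

    atlas = AtlasMatrix(
        pd.DataFrame(abundance, index=pd.Index(chosen, name="feature"),
                     columns=list(CELL_TYPES))
    )
    return atlas, PlantedTruth(celltype=truth_ct)


# ---------------------------------------------------------------------------
# drug / PPAR target networks


def generate_drug_networks(
    config: SyntheticStudyConfig,
) -> tuple[DrugTargetNetwork, PlantedTruth]:
    """Target sets for the five medications and three PPAR isotypes.

    Fenofibrate and PPARalpha both contain the whole planted FAO module
    (dominance); their mutual overlap is reproduced exactly as configured.
    Non-focal entities share a configurable fraction of their targets with a
    common background pool and pick up a token overlap with the FAO module.
    """
    spec = config.drug_specs
    rng = _rng(config, "drugs")
    genes = np.array(config.gene_ids)
    fao = list(config.fao_module.genes)
    sizes = spec.sizes
    for entity in DRUGS + PPAR_ISOTYPES:
        if entity not in sizes:
            raise ValueError(f"no target-set size configured for {entity!r}")

    non_module = [g for g in genes if g not in set(fao)]
    rng.shuffle(non_module)
    pool_size = max(sizes.values())
    shared_pool = non_module[:pool_size]
    rest = non_module[pool_size:]
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        out = rest[cursor: cursor + n]
        if len(out) < n:
            raise ValueError("gene universe too small for requested target sets")
        cursor += n
        return list(out)

    targets: dict[str, set[str]] = {}
    # fenofibrate: all FAO genes + unique filler
    if sizes["fenofibrate"] < len(fao):
        raise ValueError("fenofibrate target set smaller than the FAO module")
    targets["fenofibrate"] = set(fao) | set(take(sizes["fenofibrate"] - len(fao)))

    # PPARA: FAO genes + exact overlap with fenofibrate + filler
    k = spec.feno_ppara_overlap
    if k is None:
        k = len(fao)
    if k > min(sizes["fenofibrate"], sizes["PPARA"]):
        raise ValueError("requested fenofibrate-PPARA overlap exceeds set sizes")
    if k < len(fao):
        raise ValueError("fenofibrate-PPARA overlap cannot be below the FAO module size")
    extra_shared = [g for g in sorted(targets["fenofibrate"] - set(fao))][: k - len(fao)]
    targets["PPARA"] = set(fao) | set(extra_shared)
    targets["PPARA"] |= set(take(sizes["PPARA"] - len(targets["PPARA"])))

    n_token = min(4, len(fao))
    for entity in [d for d in DRUGS if d != "fenofibrate"] + ["PPARD", "PPARG"]:
        n = sizes[entity]
        n_shared = int(round(spec.overlap_fraction * n))
        token = (
            list(rng.choice(fao, size=n_token, replace=False))
            if spec.overlap_fraction > 0 and n_token > 0
            else []
        )
        members = set(token) | set(shared_pool[:n_shared])
        members |= set(take(n - len(members)))
        targets[entity] = members

    for entity, members in targets.items():
        if len(members) != sizes[entity]:
            raise AssertionError(f"size mismatch for {entity}")

    # expected signs: planted FAO genes are induced (+1); others random
    signs = {
        e: {g: (+1 if g in set(fao) else int(rng.choice([-1, 1]))) for g in t}
        for e, t in targets.items()
    }
    truth = PlantedTruth(responsiveness={e: sorted(t) for e, t in targets.items()})
    return DrugTargetNetwork(targets=targets, signs=signs), truth


# ---------------------------------------------------------------------------
# NMR cohort


def _background_ppm(spec: NMRSpec) -> list[float]:
    planted = [p for fam in spec.family_ppm.values() for p in fam]
    out: list[float] = []
    x = spec.ppm_min + 0.4
    while len(out) < spec.n_background and x < spec.ppm_max - 0.2:
        if all(abs(x - p) > 0.12 for p in planted + out):
            out.append(round(x, 3))
            x += 0.1
        else:
            x += 0.05
    return out


def generate_nmr_cohort(
    config: SyntheticStudyConfig,
    group_sizes: dict[str, int] | None = None,
    sample_ids: list[str] | None = None,
) -> tuple[list[Spectrum], PlantedTruth]:
    """Synthetic 1D 1H-NMR cohort with planted families and dilutions.

    Each spectrum is a sum of Gaussian (optionally Lorentzian) resonances at
    the planted ppm positions, scaled by metabolite base amplitude, the
    family x group effect, per-sample biological noise and a per-sample
    dilution factor, plus a smooth baseline and white noise. ``group_sizes``
    defaults to the four-phenotype cohort; pass e.g. the count-study groups
    to generate an animal-matched cohort.
    """
    spec = config.nmr_specs
    rng = _rng(config, "nmr")
    sizes = dict(group_sizes or spec.group_sizes)
    ppm = np.linspace(spec.ppm_min, spec.ppm_max, spec.n_points)

    peaks: list[tuple[float, str]] = [
        (p, fam) for fam, pos in spec.family_ppm.items() for p in pos
    ]
    peaks += [(p, "background") for p in _background_ppm(spec)]
    for p, _ in peaks:
        if not spec.ppm_min <= p <= spec.ppm_max:
            raise ValueError(f"planted peak at {p} ppm outside the axis")

    lo, hi = spec.amplitude_range
    base_amp = {p: rng.uniform(lo, hi) for p, _ in peaks}

    ids_iter = iter(sample_ids) if sample_ids is not None else None
    spectra: list[Spectrum] = []
    dilutions: dict[str, float] = {}
    dlo, dhi = spec.dilution_range
    for group, n in sizes.items():
        for i in range(n):
            sid = next(ids_iter) if ids_iter else f"{group}_{i + 1}"
            dil = np.exp(rng.uniform(np.log(dlo), np.log(dhi)))
            dilutions[sid] = float(dil)
            signal = np.zeros_like(ppm)
            for p, fam in peaks:
                eff = spec.family_effects[fam].get(group)
                if eff is None:
                    raise ValueError(f"no {fam!r} effect configured for group {group!r}")
                amp = base_amp[p] * eff * np.exp(rng.normal(0.0, spec.biological_cv)) * dil
                if spec.lorentzian:
                    shape = 1.0 / (1.0 + ((ppm - p) / spec.peak_sigma) ** 2)
                else:
                    shape = np.exp(-0.5 * ((ppm - p) / spec.peak_sigma) ** 2)
                signal += amp * shape
            # smooth baseline: slow polynomial drift plus one broad hump
            t = (ppm - spec.ppm_min) / (spec.ppm_max - spec.ppm_min)
            c = rng.normal(0.0, 1.0, 3)
            hump_pos = rng.uniform(3.0, 7.0)
            baseline = spec.baseline_amplitude * (
                0.5 + 0.3 * c[0] * t + 0.2 * c[1] * t**2 + 0.2 * c[2] * t**3
                + np.exp(-0.5 * ((ppm - hump_pos) / 1.5) ** 2)
            )
            noise = rng.normal(0.0, spec.noise_sd, spec.n_points) if spec.noise_sd > 0 else 0.0
            spectra.append(Spectrum(ppm.copy(), signal + baseline + noise, sid, group))

    truth = PlantedTruth(
        peak_families={f"{p:.4f}": fam for p, fam in peaks},
        family_group_means={
            fam: dict(effects) for fam, effects in spec.family_effects.items()
        },
        dilution=dilutions,
    )
    return spectra, truth


# ---------------------------------------------------------------------------
# morphometry


def generate_morphometry(
    config: SyntheticStudyConfig, animal_ids: dict[str, list[str]] | None = None
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Per-animal morphometry table from group-shifted truncated normals.

    Columns: animal_id, group, glomerular_area (um^2), pfpf (per 8 um GBM),
    gbm_thickness (nm), mito_area (um^2), mito_major (um). Values are
    resampled until positive (truncation at zero).
    """
    spec = config.morphometry
    rng = _rng(config, "morphometry")
    for par, sd in spec.sds.items():
        if sd < 0:
            raise ValueError(f"negative scale for {par!r}")
    rows = []
    for group, n in spec.n_per_group.items():
        if n < 1:
            raise ValueError("group sizes must be >= 1")
        ids = animal_ids[group] if animal_ids else [f"{group}_{i + 1}" for i in range(n)]
        for aid in ids:
            row = {"animal_id": aid, "group": group}
            for par in spec.means:
                mu, sd = spec.means[par][group], spec.sds[par]
                val = rng.normal(mu, sd)
                while val <= 0:
                    val = rng.normal(mu, sd)
                row[par] = float(val)
            rows.append(row)
    table = pd.DataFrame(rows)
    truth = PlantedTruth(group_means={p: dict(spec.means[p]) for p in spec.means})
    return table, truth
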