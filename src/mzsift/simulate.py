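"""Synthetic centroided LC-MS runs emulating a microsomal incubation study.

The generator reproduces the design of an in vitro metabolism experiment with
pooled human liver microsomes: three incubation groups (Blank = 0 uM,
Low = 12.5 uM, High = 25 uM substrate) in five replicates, a pooled QC sample
injected five times at the start of the sequence and then after every fifth
sample, plus duplicate substrate-blank (enzymes, no substrate) and
enzyme-blank (substrate, no enzymes) incubations. Each run contains the
parent compound, dose-dependent metabolite peaks at catalogued
biotransformation mass shifts, 13C isotopologues, a chloride-bearing dimer
adduct, a co-eluting in-source dehydro artifact, a powder impurity,
dose-independent background species, additive noise centroids, and a linear
multiplicative sensitivity drift over the injection sequence.

Every planted quantity is recorded in a ground-truth ledger so downstream
stages (peak detection, filtering, drift correction, annotation) can be
scored against known answers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chem
from .chem import C13_ABUNDANCE, C13_SPACING, ElementalFormula, IonSpecies, PROTONATED
from .spectra import GROUPS, SpectrumRun

__all__ = [
    "CompoundSpec",
    "SequenceDesign",
    "NoiseModel",
    "Scenario",
    "Study",
    "default_scenario",
    "build_sequence",
    "simulate_run",
    "simulate_study",
]

#: Sample types derived from the incubation groups plus the two blank checks.
_ALL_SLOTS = ("Blank", "Low", "High", "qc", "substrate_blank", "enzyme_blank")


@dataclass
class CompoundSpec:
    """One planted ionic species and its behaviour across the study design.

    ``multipliers`` scales ``base_abundance`` per slot (incubation group or
    blank type); the pooled QC multiplier is always the mean of the three
    incubation-group multipliers and need not be supplied. ``mz`` may be given
    directly (background species) or derived from ``formula`` + ``ion``.
    ``is_artifact_of`` pins ``rt_apex`` to the parent species' apex, the
    signature of in-source formation.
    """

    name: str
    species_class: str  # parent | metabolite | adduct | artifact | impurity | background
    rt_apex: float
    base_abundance: float
    rt_sigma: float = 4.0
    formula: ElementalFormula | None = None
    ion: IonSpecies = field(default_factory=lambda: PROTONATED)
    mz: float | None = None
    multipliers: dict[str, float] = field(default_factory=dict)
    is_artifact_of: str | None = None
    n_carbons: int | None = None

    def __post_init__(self) -> None:
        if self.rt_sigma <= 0:
            raise ValueError("rt_sigma must be positive")
        if self.mz is None:
            if self.formula is None:
                raise ValueError(f"{self.name}: need either mz or formula")
            self.mz = chem.ion_mz(chem.monoisotopic_mass(self.formula), self.ion)
        if self.n_carbons is None:
            if self.formula is not None:
                self.n_carbons = self.formula.counts.get("C", 0) * self.ion.multiplicity
            else:
                self.n_carbons = 0
        bad = [g for g, m in self.multipliers.items() if m < 0]
        if bad:
            raise ValueError(f"{self.name}: negative multipliers for {bad}")

    def multiplier(self, slot: str) -> float:
        if slot == "qc":
            return float(np.mean([self.multipliers.get(g, 0.0) for g in GROUPS]))
        return self.multipliers.get(slot, 0.0)

    def isotopologues(self, min_ratio: float = 1e-3) -> list[tuple[int, float]]:
        """(k, relative intensity) for the all-12C ion and its 13C satellites.

        M+1/M = n_C * 0.0107; M+2 uses the binomial second-order term.
        """
        out = [(0, 1.0)]
        if self.n_carbons:
            p = self.n_carbons * C13_ABUNDANCE
            for k, ratio in ((1, p), (2, p * p / 2.0)):
                if ratio >= min_ratio:
                    out.append((k, ratio))
        return out


@dataclass
class SequenceDesign:
    """Injection sequence layout: replicates, QC cadence, blank duplicates."""

    replicates: int = 5
    qc_lead_in: int = 5
    qc_every: int = 5
    blank_duplicates: int = 2
    drift_rate: float = -0.004  # fractional sensitivity change per injection

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("at least 2 replicates per group are required "
                             "for two-sample t-tests")
        if self.qc_every < 1:
            raise ValueError("qc_every must be >= 1")


@dataclass
class NoiseModel:
    """Stochastic components of a run.

    ``sigma_ppm``: centroid m/z jitter (ppm, 1 s.d.). ``bio_cv`` applies to
    incubation replicates only (pipetting/incubation variability);
    ``tech_cv`` to every injection. ``noise_per_scan`` is the expected count
    of additive noise centroids per scan, with log-normal intensities around
    ``noise_level``.
    """

    sigma_ppm: float = 1.0
    bio_cv: float = 0.05
    tech_cv: float = 0.02
    noise_per_scan: float = 15.0
    noise_level: float = 30.0
    noise_sigma_log: float = 0.5
    #: Per-scan probability of a faint carryover/chemical-background centroid
    #: at each analyte ion channel, in every run regardless of dose. This is
    #: what gap-filling integrates in samples that lack the analyte; real
    #: blank injections show the same near-channel background (injector
    #: carryover, solvent clusters), which is why reintegrated blank areas
    #: are small, positive, and highly variable.
    carryover_prob: float = 0.25

    @classmethod
    def off(cls) -> "NoiseModel":
        return cls(sigma_ppm=0.0, bio_cv=0.0, tech_cv=0.0,
                   noise_per_scan=0.0, noise_level=0.0, carryover_prob=0.0)

    @property
    def noise_floor(self) -> float:
        """Area-equivalent noise floor: noise intensity integrated over a
        nominal 10 s peak window."""
        return self.noise_level * 10.0


@dataclass
class Scenario:
    """Full study recipe: compounds, sequence design, noise, scan grid."""

    compounds: list[CompoundSpec]
    design: SequenceDesign = field(default_factory=SequenceDesign)
    noise: NoiseModel = field(default_factory=NoiseModel)
    rt_min: float = 0.0
    rt_max: float = 700.0
    scan_interval: float = 0.5
    polarity: str = "pos"

    def scan_grid(self) -> np.ndarray:
        if self.rt_max <= self.rt_min or self.scan_interval <= 0:
            raise ValueError("empty scan grid")
        n = int(round((self.rt_max - self.rt_min) / self.scan_interval)) + 1
        return self.rt_min + np.arange(n) * self.scan_interval


def default_scenario(
    *,
    design: SequenceDesign | None = None,
    noise: NoiseModel | None = None,
    n_background: int = 200,
    background_seed: int = 20190226,
) -> Scenario:
    """The default incubation scenario: an alpha-PBP-like parent (C14H19NO).

    The parent dominates the mixture (base abundance >= 100x any background
    species). Metabolites are planted at the catalogued biotransformation
    shifts with dose multipliers Low = 1x and High = 1.8x (mild saturation of
    metabolite formation at the higher substrate concentration); the parent
    itself scales 1x/2x with dose. The in-source dehydro artifact and the
    chloride dimer adduct track the parent and co-elute with it; the dehydro
    powder impurity elutes elsewhere and is present in the enzyme blank but
    not the substrate blank. Background species use a fixed inventory seed so
    the species list is identical across study seeds.
    """
    parent_formula = ElementalFormula.parse("C14H19NO")
    rules = {r.name: r for r in chem.builtin_transformations()}
    parent_A = 5.0e6

    def drug(mult_high: float = 2.0) -> dict[str, float]:
        # substrate-derived: scales with dose, present in the enzyme blank
        # (which contains substrate), absent from Blank and substrate blank
        return {"Blank": 0.0, "Low": 1.0, "High": mult_high,
                "substrate_blank": 0.0, "enzyme_blank": mult_high}

    def metab() -> dict[str, float]:
        # enzyme-formed: requires both substrate and microsomes
        return {"Blank": 0.0, "Low": 1.0, "High": 1.8,
                "substrate_blank": 0.0, "enzyme_blank": 0.0}

    compounds = [
        CompoundSpec("parent", "parent", 216.0, parent_A,
                     formula=parent_formula, multipliers=drug()),
        CompoundSpec("M-dihydro", "metabolite", 226.0, 0.15 * parent_A,
                     formula=rules["dihydro-"].apply_formula(parent_formula),
                     multipliers=metab()),
        CompoundSpec("M-oxo", "metabolite", 343.0, 0.10 * parent_A,
                     formula=rules["oxo-"].apply_formula(parent_formula),
                     multipliers=metab()),
        CompoundSpec("M-dihydro-HO", "metabolite", 205.0, 0.08 * parent_A,
                     formula=rules["dihydro-HO-"].apply_formula(parent_formula),
                     multipliers=metab()),
        CompoundSpec("M-di-HO", "metabolite", 412.0, 0.05 * parent_A,
                     formula=rules["di-HO-"].apply_formula(parent_formula),
                     multipliers=metab()),
        CompoundSpec("M-dihydro-oxo", "metabolite", 114.0, 0.04 * parent_A,
                     formula=rules["dihydro-oxo-"].apply_formula(parent_formula),
                     multipliers=metab()),
        CompoundSpec("artifact-dehydro", "artifact", 216.0, 0.06 * parent_A,
                     formula=rules["dehydro-"].apply_formula(parent_formula),
                     multipliers=drug(), is_artifact_of="parent"),
        CompoundSpec("impurity-dehydro", "impurity", 114.0, 0.02 * parent_A,
                     formula=rules["dehydro-"].apply_formula(parent_formula),
                     multipliers=drug()),
        CompoundSpec("adduct-2M2HCl", "adduct", 216.0, 0.03 * parent_A,
                     formula=parent_formula, ion=chem.DIMER_CHLORIDE,
                     multipliers=drug(), is_artifact_of="parent"),
    ]

    bg_rng = np.random.default_rng(background_seed)
    for i in range(n_background):
        compounds.append(CompoundSpec(
            f"bg{i:03d}", "background",
            rt_apex=float(bg_rng.uniform(20.0, 680.0)),
            base_abundance=float(8.0e3 * bg_rng.lognormal(0.0, 0.7)),
            rt_sigma=float(bg_rng.uniform(3.0, 6.0)),
            mz=float(bg_rng.uniform(80.0, 700.0)),
            multipliers={g: 1.0 for g in _ALL_SLOTS},
            n_carbons=0,
        ))
    return Scenario(
        compounds=compounds,
        design=design or SequenceDesign(),
        noise=noise or NoiseModel(),
    )


def build_sequence(design: SequenceDesign, seed: int) -> pd.DataFrame:
    """Randomized injection sequence with QC lead-in and cadence.

    Non-QC samples (incubation replicates plus blank duplicates) are shuffled
    with the given seed; ``qc_lead_in`` QC injections open the sequence and
    one QC follows every ``qc_every`` non-QC samples. Returns a DataFrame
    with sample_id, group, sample_type, injection_index.
    """
    rng = np.random.default_rng(seed)
    samples: list[tuple[str, str, str]] = []
    for g in GROUPS:
        for r in range(design.replicates):
            samples.append((f"{g}_{r + 1}", g, "incubation"))
    for r in range(design.blank_duplicates):
        samples.append((f"SB_{r + 1}", "substrate_blank", "substrate_blank"))
        samples.append((f"EB_{r + 1}", "enzyme_blank", "enzyme_blank"))
    order = rng.permutation(len(samples))
    shuffled = [samples[i] for i in order]

    rows: list[tuple[str, str, str, int]] = []
    idx = 0
    n_qc = 0
    for _ in range(design.qc_lead_in):
        n_qc += 1
        rows.append((f"QC_{n_qc}", "qc", "qc", idx))
        idx += 1
    for pos, (sid, grp, stype) in enumerate(shuffled, start=1):
        rows.append((sid, grp, stype, idx))
        idx += 1
        if pos % design.qc_every == 0 and pos < len(shuffled):
            n_qc += 1
            rows.append((f"QC_{n_qc}", "qc", "qc", idx))
            idx += 1
    # closing QC if the sequence length is a multiple of the cadence
    if len(shuffled) % design.qc_every == 0:
        n_qc += 1
        rows.append((f"QC_{n_qc}", "qc", "qc", idx))
    return pd.DataFrame(rows, columns=["sample_id", "group", "sample_type",
                                       "injection_index"])


def simulate_run(
    compounds: list[CompoundSpec],
    *,
    sample_id: str,
    group: str,
    sample_type: str,
    injection_index: int,
    scenario: Scenario,
    seed: int,
) -> tuple[SpectrumRun, pd.DataFrame]:
    """Simulate one injection and return the run plus its ledger rows.

    Each species with a positive multiplier contributes a Gaussian
    chromatographic profile (intensity integrates to the planted area over
    retention time), 13C isotopologues at +k * 1.003355 / z, per-centroid m/z
    jitter ~ Normal(0, sigma_ppm), a multiplicative linear sensitivity drift
    (1 + drift_rate * injection_index), and additive noise centroids at
    uniform random m/z with log-normal intensities.
    """
    grid = scenario.scan_grid()
    noise = scenario.noise
    design = scenario.design
    rng = np.random.default_rng(seed)
    drift_factor = max(0.0, 1.0 + design.drift_rate * injection_index)
    slot = group if sample_type == "incubation" else sample_type

    per_scan_mz: list[list[np.ndarray]] = [[] for _ in grid]
    per_scan_int: list[list[np.ndarray]] = [[] for _ in grid]
    ledger_rows = []

    for sp in compounds:
        mult = sp.multiplier(slot)
        if mult <= 0:
            continue
        cv = noise.bio_cv if sample_type == "incubation" else 0.0
        rep_factor = float(np.exp(rng.normal(0.0, cv))) if cv > 0 else 1.0
        tech_factor = (float(np.exp(rng.normal(0.0, noise.tech_cv)))
                       if noise.tech_cv > 0 else 1.0)
        area = sp.base_abundance * mult * rep_factor * tech_factor
        lo = np.searchsorted(grid, sp.rt_apex - 4.5 * sp.rt_sigma)
        hi = np.searchsorted(grid, sp.rt_apex + 4.5 * sp.rt_sigma, side="right")
        if hi <= lo:
            continue
        t = grid[lo:hi]
        profile = np.exp(-0.5 * ((t - sp.rt_apex) / sp.rt_sigma) ** 2) \
            / (sp.rt_sigma * np.sqrt(2.0 * np.pi))
        isotopes = sp.isotopologues()
        for k, ratio in isotopes:
            mz_k = sp.mz + k * C13_SPACING / abs(sp.ion.charge)
            inten = area * ratio * profile * drift_factor
            keep = inten >= 1.0
            if not keep.any():
                continue
            n_pts = int(keep.sum())
            if noise.sigma_ppm > 0:
                jitter = rng.normal(0.0, noise.sigma_ppm * 1e-6 * mz_k, n_pts)
            else:
                jitter = np.zeros(n_pts)
            mzs = mz_k + jitter
            scan_idx = np.arange(lo, hi)[keep]
            for j, si in enumerate(scan_idx):
                per_scan_mz[si].append(mzs[j:j + 1])
                per_scan_int[si].append(inten[keep][j:j + 1])
            ledger_rows.append({
                "sample_id": sample_id, "species": sp.name,
                "species_class": sp.species_class, "isotope_k": k,
                "mz": mz_k, "rt_apex": sp.rt_apex,
                "planted_area": area * ratio,
                "is_artifact_of": sp.is_artifact_of or "",
            })

    if noise.carryover_prob > 0:
        # faint background at every analyte channel, independent of dose
        for sp in compounds:
            if sp.species_class == "background":
                continue
            for k, _ in sp.isotopologues():
                mz_k = sp.mz + k * C13_SPACING / abs(sp.ion.charge)
                hits = np.flatnonzero(
                    rng.random(len(grid)) < noise.carryover_prob)
                if hits.size == 0:
                    continue
                jit = rng.normal(0.0, 3.0e-6 * mz_k, hits.size)
                lvl = noise.noise_level * rng.lognormal(
                    0.0, noise.noise_sigma_log, hits.size)
                for j, si in enumerate(hits):
                    per_scan_mz[si].append(np.array([mz_k + jit[j]]))
                    per_scan_int[si].append(lvl[j:j + 1])

    if noise.noise_per_scan > 0:
        counts = rng.poisson(noise.noise_per_scan, size=len(grid))
        for si, c in enumerate(counts):
            if c:
                per_scan_mz[si].append(rng.uniform(50.0, 750.0, c))
                per_scan_int[si].append(
                    noise.noise_level
                    * rng.lognormal(0.0, noise.noise_sigma_log, c))

    scans = []
    for si in range(len(grid)):
        if per_scan_mz[si]:
            mz = np.concatenate(per_scan_mz[si])
            inten = np.concatenate(per_scan_int[si])
            order = np.argsort(mz)
            scans.append((mz[order], inten[order]))
        else:
            scans.append((np.empty(0), np.empty(0)))

    run = SpectrumRun(sample_id=sample_id, group=group, sample_type=sample_type,
                      injection_index=injection_index,
                      polarity=scenario.polarity, scan_times=grid, scans=scans)
    return run, pd.DataFrame(ledger_rows)


@dataclass
class Study:
    """A simulated study: all runs, sample metadata, and the truth ledger."""

    runs: list[SpectrumRun]
    samples: pd.DataFrame
    ledger: pd.DataFrame
    scenario: Scenario
    seed: int

    @property
    def noise_floor(self) -> float:
        return self.scenario.noise.noise_floor

    def run_by_id(self, sample_id: str) -> SpectrumRun:
        for r in self.runs:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)


def simulate_study(scenario: Scenario | None = None, seed: int = 0) -> Study:
    """Simulate the full randomized injection sequence of the study design.

    Deterministic under a fixed seed; two seeds give different injection
    orders and different noise draws over the same species inventory.
    """
    scenario = scenario if scenario is not None else default_scenario()
    seq = build_sequence(scenario.design, seed)
    runs: list[SpectrumRun] = []
    ledgers = []
    base = np.random.default_rng(seed).integers(0, 2**31 - 1, size=len(seq))
    for row, run_seed in zip(seq.itertuples(index=False), base):
        run, led = simulate_run(
            scenario.compounds,
            sample_id=row.sample_id, group=row.group,
            sample_type=row.sample_type,
            injection_index=int(row.injection_index),
            scenario=scenario, seed=int(run_seed))
        runs.append(run)
        ledgers.append(led)
    ledger = pd.concat([l for l in ledgers if len(l)], ignore_index=True) \
        if ledgers else pd.DataFrame()
    return Study(runs=runs, samples=seq, ledger=ledger,
                 scenario=scenario, seed=seed)
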