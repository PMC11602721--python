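"""Seeded synthetic measurement generators.

Every pipeline stage is testable without instrument data: this module
fabricates 1H NMR spectra (sums of Lorentzians on the standard grid, plus
Gaussian noise and a small global shift drift emulating an unlocked benchtop
magnet) and LC-MS runs (Gaussian chromatographic envelopes carrying centroid
stick spectra, or constant-envelope direct-injection scans), all
deterministically derived from one campaign seed via numpy's seed-sequence
spawning.

Two ground-truth campaign scenarios are built in:

* a supramolecular screen — 3 carbonyl pyridines x 3 polytopic amines x 2
  metal ions (18 combinations), of which two self-assemble cleanly into a
  Zn4L4 cage and a Zn2L3 helicate; the cage binds 3 of the 6 guests, the
  helicate none. Failure modes include unreacted mixtures, an NMR-symmetric
  species with no matching ions, a single-charge-state MS coincidence and an
  oligomer-like forest of NMR peaks.
* a divergent (thio)urea synthesis — 3 alkyne amines x {isocyanate,
  isothiocyanate} (6 screening reactions, 5 of which condense successfully),
  followed by scale-up parity and Sonogashira/CuAAC diversification.

The generators encode the planted truth; the decision pipeline never sees it.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .chemspace import (
    BUILTIN_RULES,
    BuildingBlock,
    Formula,
    MzTable,
    Role,
    adduct_mz,
    apply_transform,
    build_lookup_table,
    enumerate_assemblies,
    mz_series,
)
from .msproc import LcmsRun, MassSpectrum
from .nmrproc import NmrSpectrum, default_grid

__all__ = [
    "SpectrumSpec",
    "SpeciesSignal",
    "LcmsSpec",
    "CampaignTruth",
    "SupramolecularBundle",
    "DivergentBundle",
    "gen_nmr",
    "gen_lcms",
    "gen_campaign",
    "supramolecular_scenario",
    "divergent_scenario",
    "default_supramolecular_blocks",
    "default_divergent_blocks",
]

# Default instrument emulation: 80 MHz field, 2 Hz natural linewidth, noise at
# 1% of the tallest peak, +-0.003 ppm global shift drift per acquisition.
DEFAULT_FIELD_MHZ = 80.0
DEFAULT_FWHM_HZ = 2.0
DEFAULT_NOISE_SD = 0.01
DEFAULT_DRIFT_PPM = 0.003
DEFAULT_RUN_LENGTH_MIN = 2.5  # 2 min gradient + 0.5 min hold
DEFAULT_SCAN_INTERVAL_MIN = 0.01
DEFAULT_CHROM_SIGMA_MIN = 0.05


@dataclass
class SpectrumSpec:
    """Recipe for one synthetic NMR spectrum."""

    peaks: list[tuple[float, float, float]]  # (ppm, relative height, FWHM in Hz)
    noise_sd: float = DEFAULT_NOISE_SD  # fraction of max peak height
    field_mhz: float = DEFAULT_FIELD_MHZ
    drift_ppm: float = DEFAULT_DRIFT_PPM  # sd of the global shift offset

    def __post_init__(self):
        for ppm, h, fwhm in self.peaks:
            if fwhm <= 0:
                raise ValueError(f"FWHM must be positive, got {fwhm}")
            if h <= 0:
                raise ValueError(f"peak height must be positive, got {h}")


def gen_nmr(
    spec: SpectrumSpec,
    seed: int | np.random.SeedSequence | np.random.Generator,
    grid: np.ndarray | None = None,
) -> NmrSpectrum:
    """Sum of Lorentzians on the standard grid + Gaussian noise; seeded."""
    rng = _as_rng(seed)
    if grid is None:
        grid = default_grid()
    drift = rng.normal(0.0, spec.drift_ppm) if spec.drift_ppm > 0 else 0.0
    y = np.zeros_like(grid)
    for ppm, h, fwhm_hz in spec.peaks:
        gamma = (fwhm_hz / spec.field_mhz) / 2.0
        x = grid - (ppm + drift)
        y += h * gamma * gamma / (x * x + gamma * gamma)
    top = max((h for _, h, _ in spec.peaks), default=1.0)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd * top, size=grid.shape)
    return NmrSpectrum(grid, y, field_mhz=spec.field_mhz)


@dataclass
class SpeciesSignal:
    """One species in an LC-MS run: elution envelope + stick spectrum."""

    rt_min: float
    width_min: float
    response: float
    sticks: list[tuple[float, float]]  # (m/z, relative intensity)


@dataclass
class LcmsSpec:
    """Recipe for one synthetic LC-MS run."""

    species: list[SpeciesSignal]
    mode: str = "gradient"
    noise_sd: float = 0.01  # fraction of the strongest stick
    run_length_min: float = DEFAULT_RUN_LENGTH_MIN
    scan_interval_min: float = DEFAULT_SCAN_INTERVAL_MIN

    def __post_init__(self):
        for sp in self.species:
            if self.mode == "gradient" and not 0 <= sp.rt_min <= self.run_length_min:
                raise ValueError(f"retention time {sp.rt_min} outside run length")
            if any(i < 0 for _, i in sp.sticks):
                raise ValueError("stick intensities must be non-negative")


def gen_lcms(
    spec: LcmsSpec,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> LcmsRun:
    """Synthesize an LC-MS run from species envelopes; seeded.

    Gradient mode: each species contributes its sticks to every scan, scaled
    by a Gaussian envelope centred at its retention time. Direct-injection
    mode: a short train of constant-envelope scans (column bypassed).
    """
    rng = _as_rng(seed)
    if spec.mode == "direct_injection":
        times = spec.scan_interval_min * np.arange(8)
    else:
        n = int(round(spec.run_length_min / spec.scan_interval_min))
        times = spec.scan_interval_min * np.arange(n + 1)
    top = max(
        (sp.response * i for sp in spec.species for _, i in sp.sticks), default=1.0
    )
    scans = []
    for t in times:
        mz_acc: dict[float, float] = {}
        for sp in spec.species:
            if spec.mode == "direct_injection":
                env = 1.0
            else:
                env = float(np.exp(-0.5 * ((t - sp.rt_min) / sp.width_min) ** 2))
                if env < 1e-6:
                    continue
            for mz, rel in sp.sticks:
                mz_acc[mz] = mz_acc.get(mz, 0.0) + sp.response * rel * env
        mzs = np.array(sorted(mz_acc), dtype=float)
        ints = np.array([mz_acc[m] for m in sorted(mz_acc)], dtype=float)
        if spec.noise_sd > 0 and ints.size:
            ints = np.maximum(ints + rng.normal(0.0, spec.noise_sd * top, ints.shape), 0.0)
        scans.append(MassSpectrum(mzs, ints))
    return LcmsRun(mode=spec.mode, times=times, scans=scans)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Ground-truth campaign scenarios
# ---------------------------------------------------------------------------


@dataclass
class CampaignTruth:
    """Planted per-reaction ground truth behind a synthetic campaign."""

    true_reactions: list[str]
    product_labels: dict[str, str] = field(default_factory=dict)
    assembly_stoichiometry: dict[str, tuple[int, int]] = field(default_factory=dict)
    binding: dict[tuple[str, str], bool] = field(default_factory=dict)


def default_supramolecular_blocks() -> dict[str, BuildingBlock]:
    """The supramolecular screening grid: 3 pyridines, 3 amines, 2 metals.

    Amine topicity follows the discovered architectures: the tritopic amine
    (tris(2-aminoethyl)amine) forms the Zn4L4 cage with pyridine-2-
    carbaldehyde; one ditopic amine forms the Zn2L3 helicate. Zn2+ hosts three
    bidentate pyridyl-imine chelates (octahedral), Cu+ two (tetrahedral).
    Counterion: triflate.
    """
    F = Formula
    return {
        "24": BuildingBlock("24", Role.CARBONYL_PYRIDINE, F("C6H5NO")),
        "25": BuildingBlock("25", Role.CARBONYL_PYRIDINE, F("C7H7NO")),
        "26": BuildingBlock("26", Role.CARBONYL_PYRIDINE, F("C6H4FNO")),
        "27": BuildingBlock("27", Role.POLYTOPIC_AMINE, F("C4H12N2O"), topicity=2),
        "28": BuildingBlock("28", Role.POLYTOPIC_AMINE, F("C6H18N4"), topicity=3),
        "29": BuildingBlock("29", Role.POLYTOPIC_AMINE, F("C6H14N2"), topicity=2),
        "Zn": BuildingBlock("Zn", Role.METAL_ION, F("Zn"), topicity=3, charge=2),
        "Cu": BuildingBlock("Cu", Role.METAL_ION, F("Cu"), topicity=2, charge=1),
        "OTf": BuildingBlock("OTf", Role.COUNTERION, F("CF3O3S"), charge=-1),
    }


def default_divergent_blocks() -> dict[str, BuildingBlock]:
    """The divergent-synthesis blocks: 3 alkyne amines, (iso)thiocyanate and
    isocyanate electrophiles, and the two diversification partners."""
    F = Formula
    return {
        "1": BuildingBlock("1", Role.ALKYNE_AMINE, F("C3H5N")),
        "2": BuildingBlock("2", Role.ALKYNE_AMINE, F("C4H7N")),
        "3": BuildingBlock("3", Role.ALKYNE_AMINE, F("C5H9N")),
        "4": BuildingBlock("4", Role.ISOTHIOCYANATE, F("C7H5NS")),
        "5": BuildingBlock("5", Role.ISOCYANATE, F("C7H5NO")),
        "12": BuildingBlock("12", Role.ARYL_HALIDE, F("C5H4BrN")),
        "18": BuildingBlock("18", Role.AZIDE, F("C10H13N5O4")),
    }


# NMR peak layouts (ppm, height, FWHM Hz) for the synthetic blocks. Pyridines:
# aromatic multiplet region + aldehyde CHO; amines: aliphatic resonances.
_SUPRA_NMR: dict[str, list[tuple[float, float, float]]] = {
    "24": [(7.55, 0.7, 2.0), (7.95, 0.8, 2.0), (8.75, 0.9, 2.0), (10.05, 1.0, 2.0)],
    "25": [(7.45, 0.7, 2.0), (7.85, 0.8, 2.0), (2.60, 1.0, 2.0), (9.95, 0.9, 2.0)],
    "26": [(7.65, 0.7, 2.0), (8.10, 0.8, 2.0), (8.60, 0.9, 2.0), (10.10, 1.0, 2.0)],
    "27": [(2.85, 1.0, 2.0), (3.50, 0.9, 2.0), (1.45, 0.5, 2.0)],
    "28": [(2.55, 1.0, 2.0), (2.75, 0.9, 2.0)],
    "29": [(2.65, 1.0, 2.0), (1.70, 0.7, 2.0), (1.25, 0.6, 2.0)],
}

# Imine-product layouts for the two true assemblies: same total peak count as
# the starting materials (symmetric architecture) but every resonance moved
# well clear (>= 0.15 ppm) of its parent; the aldehyde CHO is replaced by the
# imine CH=N and the aromatics shift on coordination.
_TRUE_ASSEMBLY_NMR: dict[str, list[tuple[float, float, float]]] = {
    "24+28+Zn": [
        (7.30, 0.7, 2.0),
        (8.20, 0.8, 2.0),
        (8.45, 0.9, 2.0),
        (8.95, 1.0, 2.0),  # CH=N
        (2.95, 1.0, 2.0),
        (3.25, 0.9, 2.0),
    ],
    "24+29+Zn": [
        (7.25, 0.7, 2.0),
        (8.15, 0.8, 2.0),
        (8.50, 0.9, 2.0),
        (9.05, 1.0, 2.0),  # CH=N
        (3.05, 1.0, 2.0),
        (2.10, 0.7, 2.0),
        (1.55, 0.6, 2.0),
    ],
}

_DIVERGENT_NMR: dict[str, list[tuple[float, float, float]]] = {
    "1": [(2.25, 0.6, 2.0), (3.40, 1.0, 2.0)],
    "2": [(2.30, 0.6, 2.0), (2.45, 0.8, 2.0), (2.85, 1.0, 2.0)],
    "3": [(2.20, 0.6, 2.0), (1.65, 0.7, 2.0), (2.75, 1.0, 2.0)],
    "4": [(7.25, 0.8, 2.0), (7.40, 1.0, 2.0)],
    "5": [(7.10, 0.8, 2.0), (7.35, 1.0, 2.0)],
}


def _urea_product_nmr(amine: str, electrophile: str) -> list[tuple[float, float, float]]:
    """(Thio)urea product layout: aliphatics move downfield, aromatics move,
    and two new NH resonances appear far from every starting resonance."""
    out: list[tuple[float, float, float]] = []
    for ppm, h, w in _DIVERGENT_NMR[amine]:
        out.append((ppm + 1.10, h, w))  # CH2/CH alpha to the new (thio)urea
    for ppm, h, w in _DIVERGENT_NMR[electrophile]:
        out.append((ppm - 0.85, h, w))
    nh = 8.55 if electrophile == "4" else 8.20
    out.append((nh, 0.9, 2.0))
    out.append((6.30, 0.8, 2.0))  # second NH
    return out


@dataclass
class SupramolecularBundle:
    """Everything the supramolecular pipeline consumes for one seed."""

    combos: list[str]
    blocks: dict[str, BuildingBlock]
    table: MzTable
    sm_nmr: dict[str, list[NmrSpectrum]]
    screen_nmr: dict[str, NmrSpectrum]
    screen_ms: dict[str, LcmsRun]
    replicate_nmr: dict[str, list[NmrSpectrum]]
    replicate_ms: dict[str, list[LcmsRun]]
    host_nmr: dict[str, NmrSpectrum]
    guest_nmr: dict[tuple[str, str], NmrSpectrum]
    guests: list[str]
    replicate_count: int
    truth: CampaignTruth


@dataclass
class DivergentBundle:
    """Everything the divergent pipeline consumes for one seed."""

    reactions: list[str]
    blocks: dict[str, BuildingBlock]
    sm_nmr: dict[str, list[NmrSpectrum]]
    screen_nmr: dict[str, NmrSpectrum]
    screen_lcms: dict[str, LcmsRun]
    expected_mz: dict[str, list[tuple[str, float]]]
    scaleup_nmr: dict[str, NmrSpectrum]
    scaleup_lcms: dict[str, LcmsRun]
    diversifications: list[str]
    diversify_lcms: dict[tuple[str, str], LcmsRun]
    diversify_expected: dict[tuple[str, str], list[tuple[str, float]]]
    truth: CampaignTruth


@dataclass
class _SupraScenario:
    kind: str
    truth: CampaignTruth
    noise_sd: float
    replicate_count: int
    guests: list[str]


@dataclass
class _DivergentScenario:
    kind: str
    truth: CampaignTruth
    noise_sd: float
    failed_reaction: str


def supramolecular_scenario(
    noise_sd: float = DEFAULT_NOISE_SD,
    replicate_count: int = 6,
) -> _SupraScenario:
    """The default supramolecular ground truth: 2 true assemblies out of 18
    combinations; the cage binds guests g1-g3, the helicate binds none."""
    guests = [f"g{i}" for i in range(1, 7)]
    truth = CampaignTruth(
        true_reactions=["24+28+Zn", "24+29+Zn"],
        assembly_stoichiometry={"24+28+Zn": (4, 4), "24+29+Zn": (2, 3)},
        binding={
            **{("24+28+Zn", g): g in ("g1", "g2", "g3") for g in guests},
            **{("24+29+Zn", g): False for g in guests},
        },
    )
    return _SupraScenario("supramolecular", truth, noise_sd, replicate_count, guests)


def divergent_scenario(
    noise_sd: float = DEFAULT_NOISE_SD,
    failed_reaction: str = "3+4",
) -> _DivergentScenario:
    """The default divergent ground truth: 5 of the 6 (thio)urea
    condensations succeed; one amine/isothiocyanate pair does not react."""
    reactions = [f"{a}+{e}" for a in ("1", "2", "3") for e in ("4", "5")]
    if failed_reaction not in reactions:
        raise ValueError(f"failed_reaction must be one of {reactions}")
    truth = CampaignTruth(
        true_reactions=[r for r in reactions if r != failed_reaction],
    )
    return _DivergentScenario("divergent", truth, noise_sd, failed_reaction)


def gen_campaign(scenario, seed: int):
    """Generate the full measurement bundle for a scenario; seeded.

    One campaign seed is spawned into independent substreams per measurement,
    so the whole bundle is reproduced by a single integer.
    """
    if scenario.kind == "supramolecular":
        return _gen_supramolecular(scenario, seed)
    if scenario.kind == "divergent":
        return _gen_divergent(scenario, seed)
    raise ValueError(f"unknown scenario kind {scenario.kind!r}")


def _spawn(seed: int, *key: str) -> np.random.Generator:
    # stable named substream: campaign seed + CRC of the key path
    h = zlib.crc32("|".join(key).encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(h,)))


def _junk_sticks(
    rng: np.random.Generator, table: MzTable, n: int, avoid_margin: float
) -> list[tuple[float, float]]:
    """Random background sticks guaranteed clear of every table value."""
    all_mz = np.array([mz for e in table.entries for _, _, mz in e.ladder])
    out = []
    while len(out) < n:
        cand = float(rng.uniform(150.0, 1900.0))
        if np.min(np.abs(all_mz - cand)) > avoid_margin:
            out.append((cand, float(rng.uniform(0.2, 1.0))))
    return out


def _gen_supramolecular(sc: _SupraScenario, seed: int) -> SupramolecularBundle:
    blocks = default_supramolecular_blocks()
    pyridines = [blocks[i] for i in ("24", "25", "26")]
    amines = [blocks[i] for i in ("27", "28", "29")]
    metals = [blocks[i] for i in ("Zn", "Cu")]
    table = build_lookup_table(
        pyridines, amines, metals, blocks["OTf"], max_metals={"Zn": 10, "Cu": 12}
    )
    combos = [
        f"{p.id}+{a.id}+{m.id}"
        for p, a, m in itertools.product(pyridines, amines, metals)
    ]

    def nmr(peaks, *key, noise=None):
        spec = SpectrumSpec(peaks, noise_sd=sc.noise_sd if noise is None else noise)
        return gen_nmr(spec, _spawn(seed, *key))

    sm_nmr: dict[str, list[NmrSpectrum]] = {}
    screen_nmr: dict[str, NmrSpectrum] = {}
    screen_ms: dict[str, LcmsRun] = {}
    truth = sc.truth

    # special false combos exercising individual failure modes
    nmr_only_combo = "25+28+Zn"  # symmetric-looking NMR, no matching ions
    one_state_combo = "26+27+Cu"  # exactly one charge-ladder coincidence
    oligomer_combo = "25+29+Cu"  # peak forest

    for combo in combos:
        pid, aid, mid = combo.split("+")
        sm_nmr[combo] = [
            nmr(_SUPRA_NMR[pid], combo, "sm", pid),
            nmr(_SUPRA_NMR[aid], combo, "sm", aid),
        ]
        rng_ms = _spawn(seed, combo, "ms")
        if combo in truth.true_reactions:
            screen_nmr[combo] = nmr(_TRUE_ASSEMBLY_NMR[combo], combo, "rxn")
            m, l = truth.assembly_stoichiometry[combo]
            metal, pyr, am = blocks[mid], blocks[pid], blocks[aid]
            species = next(
                s
                for s in enumerate_assemblies(pyr, am, metal, 12)
                if s.metal_count == m and s.ligand_count == l
            )
            ladder = mz_series(species, blocks["OTf"])
            usable = [(z, n, mz) for z, n, mz in ladder if 150.0 <= mz <= 1900.0]
            chosen = usable[:: max(1, len(usable) // 4)][:4]
            sticks = [(mz, 1.0 - 0.15 * k) for k, (_, _, mz) in enumerate(chosen)]
            sticks += _junk_sticks(rng_ms, table, 2, avoid_margin=1.5)
            truth.product_labels[combo] = species.label
        elif combo == oligomer_combo:
            rng_pk = _spawn(seed, combo, "peaks")
            peaks = [
                (float(p), float(rng_pk.uniform(0.3, 1.0)), 2.0)
                for p in np.sort(rng_pk.uniform(1.0, 9.5, size=16))
            ]
            screen_nmr[combo] = nmr(peaks, combo, "rxn")
            sticks = _junk_sticks(rng_ms, table, 5, avoid_margin=1.5)
        elif combo == nmr_only_combo:
            pid_, aid_ = combo.split("+")[:2]
            shifted = [
                (ppm + 0.30, h, w) for ppm, h, w in (_SUPRA_NMR[pid_] + _SUPRA_NMR[aid_])
            ]
            screen_nmr[combo] = nmr(shifted, combo, "rxn")
            sticks = _junk_sticks(rng_ms, table, 4, avoid_margin=1.5)
        else:
            # unreacted: starting materials at their original shifts
            peaks = _SUPRA_NMR[pid] + _SUPRA_NMR[aid]
            screen_nmr[combo] = nmr(peaks, combo, "rxn")
            sticks = _junk_sticks(rng_ms, table, 4, avoid_margin=1.5)
            if combo == one_state_combo:
                entry = next(e for e in table.entries if e.combination == combo)
                usable = [mz for _, _, mz in entry.ladder if 150.0 <= mz <= 1900.0]
                if usable:
                    sticks.append((usable[0], 0.8))
        screen_ms[combo] = gen_lcms(
            LcmsSpec(
                species=[SpeciesSignal(0.0, 1.0, 1.0, sticks)],
                mode="direct_injection",
                noise_sd=sc.noise_sd,
            ),
            _spawn(seed, combo, "ms-noise"),
        )

    replicate_nmr: dict[str, list[NmrSpectrum]] = {}
    replicate_ms: dict[str, list[LcmsRun]] = {}
    host_nmr: dict[str, NmrSpectrum] = {}
    guest_nmr: dict[tuple[str, str], NmrSpectrum] = {}
    for combo in truth.true_reactions:
        peaks = _TRUE_ASSEMBLY_NMR[combo]
        m, l = truth.assembly_stoichiometry[combo]
        pid, aid, mid = combo.split("+")
        species = next(
            s
            for s in enumerate_assemblies(blocks[pid], blocks[aid], blocks[mid], 12)
            if s.metal_count == m and s.ligand_count == l
        )
        ladder = mz_series(species, blocks["OTf"])
        usable = [(z, n, mz) for z, n, mz in ladder if 150.0 <= mz <= 1900.0]
        chosen = usable[:: max(1, len(usable) // 4)][:4]
        sticks = [(mz, 1.0 - 0.15 * k) for k, (_, _, mz) in enumerate(chosen)]
        replicate_nmr[combo] = [
            gen_nmr(SpectrumSpec(peaks, noise_sd=sc.noise_sd), _spawn(seed, combo, "rep", str(k)))
            for k in range(sc.replicate_count)
        ]
        replicate_ms[combo] = [
            gen_lcms(
                LcmsSpec(
                    species=[SpeciesSignal(0.0, 1.0, 1.0, list(sticks))],
                    mode="direct_injection",
                    noise_sd=sc.noise_sd,
                ),
                _spawn(seed, combo, "rep-ms", str(k)),
            )
            for k in range(sc.replicate_count)
        ]
        host_nmr[combo] = gen_nmr(
            SpectrumSpec(peaks, noise_sd=sc.noise_sd), _spawn(seed, combo, "host")
        )
        for g in sc.guests:
            if truth.binding[(combo, g)]:
                shifted = [
                    (ppm + 0.06 if ppm >= 6.0 else ppm, h, w) for ppm, h, w in peaks
                ]
            else:
                shifted = peaks
            guest_nmr[(combo, g)] = gen_nmr(
                SpectrumSpec(shifted, noise_sd=sc.noise_sd),
                _spawn(seed, combo, "guest", g),
            )

    return SupramolecularBundle(
        combos=combos,
        blocks=blocks,
        table=table,
        sm_nmr=sm_nmr,
        screen_nmr=screen_nmr,
        screen_ms=screen_ms,
        replicate_nmr=replicate_nmr,
        replicate_ms=replicate_ms,
        host_nmr=host_nmr,
        guest_nmr=guest_nmr,
        guests=list(sc.guests),
        replicate_count=sc.replicate_count,
        truth=truth,
    )


def _divergent_product_lcms(
    product_mz: list[tuple[str, float]],
    sm_mz: list[list[tuple[str, float]]],
    has_product: bool,
    noise_sd: float,
    rng: np.random.Generator,
) -> LcmsRun:
    species = []
    if has_product:
        species.append(
            SpeciesSignal(1.20, DEFAULT_CHROM_SIGMA_MIN, 1.0, [(mz, 1.0) for _, mz in product_mz])
        )
        responses = [0.08, 0.06]  # leftover starting materials, below main-peak cut
    else:
        responses = [1.0, 0.8]
    for k, sm in enumerate(sm_mz):
        species.append(
            SpeciesSignal(
                0.45 + 0.3 * k,
                DEFAULT_CHROM_SIGMA_MIN,
                responses[k % len(responses)],
                [(mz, 1.0) for _, mz in sm],
            )
        )
    return gen_lcms(LcmsSpec(species=species, noise_sd=noise_sd), rng)


def _gen_divergent(sc: _DivergentScenario, seed: int) -> DivergentBundle:
    blocks = default_divergent_blocks()
    reactions = [f"{a}+{e}" for a in ("1", "2", "3") for e in ("4", "5")]
    truth = sc.truth
    sm_nmr: dict[str, list[NmrSpectrum]] = {}
    screen_nmr: dict[str, NmrSpectrum] = {}
    screen_lcms: dict[str, LcmsRun] = {}
    expected: dict[str, list[tuple[str, float]]] = {}
    scaleup_nmr: dict[str, NmrSpectrum] = {}
    scaleup_lcms: dict[str, LcmsRun] = {}
    products = {}

    def nmr(peaks, *key):
        return gen_nmr(SpectrumSpec(peaks, noise_sd=sc.noise_sd), _spawn(seed, *key))

    for rid in reactions:
        aid, eid = rid.split("+")
        rule = BUILTIN_RULES["thiourea" if eid == "4" else "urea"]
        product = apply_transform(rule, [blocks[aid], blocks[eid]])
        products[rid] = product
        expected[rid] = adduct_mz(product)
        sm_nmr[rid] = [nmr(_DIVERGENT_NMR[aid], rid, "sm", aid), nmr(_DIVERGENT_NMR[eid], rid, "sm", eid)]
        is_true = rid in truth.true_reactions
        if is_true:
            prod_peaks = _urea_product_nmr(aid, eid)
            screen_nmr[rid] = nmr(prod_peaks, rid, "rxn")
            truth.product_labels[rid] = product.id
        else:
            screen_nmr[rid] = nmr(_DIVERGENT_NMR[aid] + _DIVERGENT_NMR[eid], rid, "rxn")
        sm_mz = [adduct_mz(blocks[aid])[:1], adduct_mz(blocks[eid])[:1]]
        screen_lcms[rid] = _divergent_product_lcms(
            expected[rid][:2], sm_mz, is_true, sc.noise_sd, _spawn(seed, rid, "lcms")
        )
        if is_true:
            scaleup_nmr[rid] = nmr(_urea_product_nmr(aid, eid), rid, "scaleup")
            scaleup_lcms[rid] = _divergent_product_lcms(
                expected[rid][:2], sm_mz, True, sc.noise_sd, _spawn(seed, rid, "scaleup-lcms")
            )

    diversifications = ["sonogashira:12", "cuaac:18"]
    diversify_lcms: dict[tuple[str, str], LcmsRun] = {}
    diversify_expected: dict[tuple[str, str], list[tuple[str, float]]] = {}
    for rid in truth.true_reactions:
        for div in diversifications:
            rule_name, partner = div.split(":")
            final = apply_transform(BUILTIN_RULES[rule_name], [products[rid], blocks[partner]])
            diversify_expected[(rid, div)] = adduct_mz(final)
            diversify_lcms[(rid, div)] = _divergent_product_lcms(
                diversify_expected[(rid, div)][:2],
                [adduct_mz(products[rid])[:1], adduct_mz(blocks[partner])[:1]],
                True,
                sc.noise_sd,
                _spawn(seed, rid, div, "lcms"),
            )

    return DivergentBundle(
        reactions=reactions,
        blocks=blocks,
        sm_nmr=sm_nmr,
        screen_nmr=screen_nmr,
        screen_lcms=screen_lcms,
        expected_mz=expected,
        scaleup_nmr=scaleup_nmr,
        scaleup_lcms=scaleup_lcms,
        diversifications=diversifications,
        diversify_lcms=diversify_lcms,
        diversify_expected=diversify_expected,
        truth=truth,
    )
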