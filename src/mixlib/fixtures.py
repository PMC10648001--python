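"""Synthetic mixture designs and DDA runs with known ground truth.

The generator emulates the screening study this package is built for:
ten mixes of 95-365 substances (with replicate subsets shared between
mixes and deliberately planted same-formula isobar pairs), acquired as one
run per mix x ionization mode x nominal collision energy.  Each run holds
MS1 scans on a fixed cycle with Gaussian chromatographic profiles plus
baseline noise, and inclusion-list DDA MS2 scans triggered near each
compound's apex whose fragment peaks come from true sub-formulas of the
precursor ion, shifted by a planted m/z-error curve.

Everything is driven by a seeded generator: a fixed seed reproduces the
dataset byte for byte.  Ground truth (true retention times, apex
intensities, planted fragment formulas, planted QC violations and the
true peak-to-compound mapping for isobar groups) is returned alongside and
can be written as JSON.

Compound structures are synthetic but chemically valid: homologous series
(alcohols, acids, amines, esters, amides, aromatics, ...) whose members
are spaced in mass so that, except for planted isobar pairs, no two
compounds of one mix fall within the precursor isolation window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import chem
from .annotate import ion_mz_of_formula
from .msio import (CompoundEntry, MixDesign, Run, Scan, Settings,
                   write_run, write_settings)

__all__ = [
    "SimParams",
    "GroundTruth",
    "CompoundSim",
    "TABLE1_SIZES",
    "generate_compound_pool",
    "generate_design",
    "simulate_run",
    "two_mix_isobar_scenario",
    "write_dataset",
    "default_settings",
]

#: Mix sizes of the ten-mixture screening design.
TABLE1_SIZES = {
    "499": 95, "500": 95, "501": 95, "502": 95,
    "503": 185, "504": 185, "505": 365, "506": 365,
    "507": 95, "508": 365,
}
#: Mixes whose membership includes the replicate set of another mix.
TABLE1_REPLICATES = {"503": "499", "505": "499"}

CE_LEVELS = (15.0, 30.0, 45.0, 60.0, 75.0, 90.0)


@dataclass
class SimParams:
    """Simulation conditions for one dataset."""

    rt_min: float = 1.0  # minutes
    rt_max: float = 15.5
    ms1_interval: float = 0.02  # minutes per MS1 cycle
    peak_sigma: float = 0.05  # chromatographic sigma, minutes
    apex_min: float = 2.0e5  # counts
    apex_max: float = 5.0e6
    noise_level: float = 300.0  # baseline centroid intensity scale
    noise_peaks_per_scan: int = 10
    #: planted mass-error curve, ppm as a function of m/z; the default is a
    #: gentle linear drift that stays within the 2.5 ppm screening window
    #: over the simulated mass range while remaining recoverable by the
    #: recalibration stage
    error_ppm: Callable[[float], float] = field(
        default=lambda mz: 0.8 + 0.0015 * (mz - 100.0))
    ce_levels: Tuple[float, ...] = CE_LEVELS
    isolation_window: float = 1.0  # Da
    ms2_per_compound: int = 3
    fragments_per_spectrum: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.peak_sigma <= 0:
            raise ValueError("peak_sigma must be positive")
        if not self.ce_levels:
            raise ValueError("at least one collision energy level")


@dataclass
class CompoundSim:
    """Per-compound ground truth within one dataset."""

    rt: float  # minutes
    apex: float  # counts
    detectable: bool = True
    #: planted QC violation, one of None|"intensity"|"snr"|"ms2_present"|
    #: "rt_shift"
    violation: Optional[str] = None


@dataclass
class GroundTruth:
    compounds: Dict[str, CompoundSim] = field(default_factory=dict)
    #: per mix: list of (rt, compound_id) for every planted peak
    peak_map: Dict[str, List[Tuple[float, str]]] = field(default_factory=dict)
    #: per compound x CE: planted fragment ion formulas
    fragments: Dict[str, Dict[str, List[str]]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "compounds": {k: asdict(v) for k, v in self.compounds.items()},
            "peak_map": self.peak_map,
            "fragments": self.fragments,
        }, sort_keys=True, indent=0)


# ---------------------------------------------------------------------------
# Compound pool


_FAMILIES: List[Tuple[str, Callable[[int], str]]] = [
    ("alkan-1-ol", lambda n: "C" * n + "O"),
    ("alkanoic acid", lambda n: "C" * (n - 1) + "C(=O)O"),
    ("alkan-1-amine", lambda n: "C" * n + "N"),
    ("alkanamide", lambda n: "C" * (n - 1) + "C(N)=O"),
    ("alkanenitrile", lambda n: "C" * (n - 1) + "C#N"),
    ("methyl alkanoate", lambda n: "C" * (n - 2) + "C(=O)OC"),
    ("alkane-1,2-diol", lambda n: "OC" + "C" * (n - 2) + "O" if n >= 3
     else "OCCO"),
    ("alkylbenzene", lambda n: "c1ccccc1" + "C" * n),
    ("phenyl alkan-1-ol", lambda n: "c1ccccc1" + "C" * n + "O"),
    ("alkyl phenyl ether", lambda n: "c1ccccc1O" + "C" * n),
    ("alkanethiol", lambda n: "C" * n + "S"),
    ("chloroalkane", lambda n: "C" * n + "Cl"),
    ("alkane-1-sulfonamide", lambda n: "C" * n + "S(N)(=O)=O"),
    ("pyridinylalkane", lambda n: "c1ccncc1" + "C" * n),
    ("alkyl acetamide", lambda n: "CC(=O)N" + "C" * n),
    ("fluoroalkanol", lambda n: "FC" + "C" * (n - 1) + "O" if n >= 2
     else "FCO"),
]


def generate_compound_pool(count: int, start_n: int = 3
                           ) -> List[CompoundEntry]:
    """Deterministic pool of valid, structurally distinct compounds.

    Families are interleaved over increasing chain length, giving a wide,
    roughly uniform spread of monoisotopic masses.
    """
    entries: List[CompoundEntry] = []
    seen_smiles = set()
    n = start_n
    serial = 1
    while len(entries) < count:
        for family, smiles_of in _FAMILIES:
            if len(entries) >= count:
                break
            smiles = smiles_of(n)
            try:
                entry = CompoundEntry.from_smiles(
                    f"SYN{serial:06d}", f"{family} C{n}", smiles)
            except ValueError:
                continue
            from rdkit import Chem as _Chem

            canonical = _Chem.MolToSmiles(
                _Chem.MolFromSmiles(entry.ms_ready_smiles))
            if canonical in seen_smiles:
                continue
            seen_smiles.add(canonical)
            entries.append(entry)
            serial += 1
        n += 1
    return entries


_ISOBAR_TEMPLATES: List[Tuple[str, str, str, str]] = [
    # (name A, smiles A, name B, smiles B) -- same molecular formula
    ("2,2-dimethyl-2,3-dihydro-1-benzofuran-7-amine", "CC1(C)Cc2cccc(N)c2O1",
     "N-(2,4-dimethylphenyl)acetamide", "CC(=O)Nc1ccc(C)cc1C"),
    ("butan-1-ol", "CCCCO", "2-methylpropan-1-ol", "CC(C)CO"),
    ("pentan-1-amine", "CCCCCN", "2-methylbutan-1-amine", "CCC(C)CN"),
    ("hexanoic acid", "CCCCCC(=O)O", "4-methylpentanoic acid",
     "CC(C)CCC(=O)O"),
    ("heptan-1-ol", "CCCCCCCO", "5-methylhexan-1-ol", "CC(C)CCCCO"),
    ("octanamide", "CCCCCCCC(N)=O", "6-methylheptanamide", "CC(C)CCCCC(N)=O"),
]


def _isobar_pair(index: int, serial_base: int
                 ) -> Tuple[CompoundEntry, CompoundEntry]:
    name_a, smi_a, name_b, smi_b = _ISOBAR_TEMPLATES[
        index % len(_ISOBAR_TEMPLATES)]
    a = CompoundEntry.from_smiles(f"ISO{serial_base:04d}A", name_a, smi_a)
    b = CompoundEntry.from_smiles(f"ISO{serial_base:04d}B", name_b, smi_b)
    assert chem.hill_formula(a.formula) == chem.hill_formula(b.formula)
    return a, b


@dataclass
class IsobarPlanSpec:
    """One planted isobar pair.

    ``shared_mixes`` both members; ``solo_mix`` (optional) carries only
    member A and thereby disambiguates the pair by RT anchoring.
    """

    shared_mixes: Tuple[str, ...]
    solo_mix: Optional[str] = None


def generate_design(sizes: Optional[Mapping[str, int]] = None,
                    replicate_plan: Optional[Mapping[str, str]] = None,
                    isobar_plan: Sequence[IsobarPlanSpec] = (),
                    seed: int = 0,
                    min_sep_da: float = 1.2
                    ) -> Tuple[List[CompoundEntry], MixDesign]:
    """Compound list plus mix design.

    Defaults reproduce the ten-mix screening layout (sizes per
    :data:`TABLE1_SIZES`, replicate subsets per :data:`TABLE1_REPLICATES`).
    Compounds within one mix are packed so consecutive [M+H]+ m/z values
    differ by more than ``min_sep_da`` -- i.e. no accidental isobars --
    before the requested isobar pairs are planted on top.
    """
    if sizes is None:
        sizes = dict(TABLE1_SIZES)
        if replicate_plan is None:
            replicate_plan = dict(TABLE1_REPLICATES)
    sizes = dict(sizes)
    replicate_plan = dict(replicate_plan or {})
    for mix, source in replicate_plan.items():
        if source not in sizes:
            raise ValueError(f"replicate source {source!r} not in design")
        if sizes[mix] < sizes[source]:
            raise ValueError(f"mix {mix} too small for replicate of {source}")

    rng = np.random.default_rng(seed)
    n_new = {}
    for mix, size in sizes.items():
        n_new[mix] = size - (sizes[replicate_plan[mix]]
                             if mix in replicate_plan else 0)
    # the separation constraint skips pool members that fall too close in
    # mass, so provision generously
    pool = generate_compound_pool(3 * sum(n_new.values()) + 96)
    pool = sorted(pool, key=lambda e: e.monoisotopic_mass)

    design = MixDesign()
    compounds: Dict[str, CompoundEntry] = {}
    cursor = 0
    # round-robin packing: walking the mass-sorted pool guarantees
    # monotonically growing m/z per mix; enforce the separation on the fly
    for mix in sorted(sizes):
        members: List[CompoundEntry] = []
        last_mz = -np.inf
        i = cursor
        while len(members) < n_new[mix] and i < len(pool):
            entry = pool[i]
            mz = entry.ion_mz("[M+H]+")
            if mz - last_mz > min_sep_da:
                members.append(entry)
                pool.pop(i)
                last_mz = mz
            else:
                i += 1
        if len(members) < n_new[mix]:
            raise ValueError(
                f"cannot pack mix {mix}: pool exhausted "
                f"({len(members)}/{n_new[mix]})")
        design.mixes[mix] = {e.identifier for e in members}
        for e in members:
            compounds[e.identifier] = e
    for mix, source in replicate_plan.items():
        design.mixes[mix] |= design.mixes[source]

    for k, spec in enumerate(isobar_plan):
        a, b = _isobar_pair(k, k + 1)
        compounds[a.identifier] = a
        compounds[b.identifier] = b
        for mix in spec.shared_mixes:
            design.mixes.setdefault(mix, set()).update(
                {a.identifier, b.identifier})
        if spec.solo_mix is not None:
            design.mixes.setdefault(spec.solo_mix, set()).add(a.identifier)
    _ = rng  # reserved for future randomized packing
    order = {e.identifier: i for i, e in enumerate(
        sorted(compounds.values(), key=lambda e: e.identifier))}
    entries = sorted(compounds.values(), key=lambda e: order[e.identifier])
    return entries, design


# ---------------------------------------------------------------------------
# Ground-truth assignment


def assign_ground_truth(entries: Sequence[CompoundEntry],
                        design: MixDesign, params: SimParams,
                        violations: Optional[Mapping[str, str]] = None
                        ) -> GroundTruth:
    """Draw per-compound retention times and apex intensities.

    RTs are spread over the gradient on a jittered grid so co-elution only
    happens when planted; a compound keeps one RT across all mixes (same
    chromatography).  ``violations`` maps compound ids to a planted QC
    failure mode.
    """
    rng = np.random.default_rng(params.seed + 1)
    violations = dict(violations or {})
    truth = GroundTruth()
    ids = sorted({e.identifier for e in entries})
    span = params.rt_max - params.rt_min - 2.0 * params.peak_sigma
    slots = np.linspace(params.rt_min + params.peak_sigma,
                        params.rt_min + params.peak_sigma + span, len(ids))
    rng.shuffle(slots)
    grid = params.ms1_interval
    for ident, slot in zip(ids, slots):
        rt = round(float(slot) / grid) * grid
        apex = float(rng.uniform(params.apex_min, params.apex_max))
        violation = violations.get(ident)
        if violation == "intensity":
            apex = 5.0e4
        elif violation == "rt_shift":
            # the shifted MS2 must still fit inside the gradient
            rt = min(rt, round((params.rt_max - 1.0) / grid) * grid)
        truth.compounds[ident] = CompoundSim(
            rt=rt, apex=apex,
            detectable=violation is None,
            violation=violation,
        )
    for mix in sorted(design.mixes):
        truth.peak_map[mix] = sorted(
            (truth.compounds[cid].rt, cid)
            for cid in design.compounds_in(mix))
    return truth


def plant_fragments(entries: Sequence[CompoundEntry], params: SimParams,
                    adduct="[M+H]+") -> Dict[str, Dict[str, List[str]]]:
    """Choose true fragment sub-formulas per compound and CE level.

    Fragments are random element-wise sub-multisets of the precursor ion
    formula with RDBE >= -0.5 and m/z >= 50; higher collision energies
    favour lower-mass fragments.  The precursor ion itself is always
    retained (it dominates at low CE).
    """
    rng = np.random.default_rng(params.seed + 2)
    adduct = chem.get_adduct(adduct) if isinstance(adduct, str) else adduct
    out: Dict[str, Dict[str, List[str]]] = {}
    for entry in sorted(entries, key=lambda e: e.identifier):
        ion = chem.ion_formula(entry.formula, adduct)
        syms = sorted(ion)
        candidates: List[Dict[str, int]] = []
        for _ in range(200):
            c = {s: int(rng.integers(0, ion[s] + 1)) for s in syms}
            c = {s: n for s, n in c.items() if n > 0}
            if not c or chem.rdbe(c) < -0.5:
                continue
            mz = ion_mz_of_formula(c, +1 if adduct.charge > 0 else -1)
            if 50.0 <= mz < entry.ion_mz(adduct) - 1.0:
                candidates.append(c)
            if len(candidates) >= 4 * params.fragments_per_spectrum:
                break
        unique = {chem.hill_formula(c): c for c in candidates}
        pool = sorted(unique)
        per_ce: Dict[str, List[str]] = {}
        for ce in params.ce_levels:
            take = min(len(pool), params.fragments_per_spectrum - 1)
            chosen = list(rng.choice(pool, size=take, replace=False)) \
                if take else []
            per_ce[f"{ce:g}"] = sorted(chosen) + [chem.hill_formula(ion)]
        out[entry.identifier] = per_ce
    return out


# ---------------------------------------------------------------------------
# Run simulation


def _gaussian(t: np.ndarray, rt: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - rt) / sigma) ** 2)


def _apply_error(mz: float, params: SimParams) -> float:
    return mz * (1.0 + params.error_ppm(mz) * 1e-6)


def _run_seed(params: SimParams, mix: str, mode: str, ce: float) -> int:
    import zlib

    tag = f"{mix}|{mode}|{ce:g}".encode()
    return ((params.seed + 3) * 1_000_003 + zlib.crc32(tag)) % (2**31)


def simulate_run(entries: Sequence[CompoundEntry], mix: str, mode: str,
                 ce: float, params: SimParams, truth: GroundTruth,
                 adduct="[M+H]+") -> Run:
    """One DDA acquisition of one mix at one collision energy.

    MS1 scans lie on a fixed RT grid; each detectable compound contributes
    a Gaussian EIC profile (with +/-1% shot-noise jitter) at its
    mass-error-shifted ion m/z.  MS2 scans are inserted after the MS1 scan
    nearest the apex (inclusion-list behaviour: only mix members trigger),
    with fragment peaks generated from the planted true sub-formulas,
    shifted by the same error curve.  CE-dependent intensity shifts favour
    low-mass fragments at high CE.

    Planted QC violations express themselves here: ``intensity`` lowers
    the apex (set in the ground truth), ``snr`` adds a dense elevated
    baseline to the compound's m/z channel outside the peak region,
    ``ms2_present`` suppresses MS2 triggering and ``rt_shift`` moves every
    MS2 scan 0.7 min past the apex.
    """
    adduct = chem.get_adduct(adduct) if isinstance(adduct, str) else adduct
    rng = np.random.default_rng(_run_seed(params, mix, mode, ce))
    members = list(entries)
    times = np.arange(params.rt_min, params.rt_max, params.ms1_interval)
    n_times = times.size
    sim_of = truth.compounds

    # per-compound observed ion m/z (with planted mass error)
    obs_mz = {e.identifier: _apply_error(e.ion_mz(adduct), params)
              for e in members}

    # per-scan MS1 peak lists, built compound by compound (vectorized)
    scan_mz: List[List[float]] = [[] for _ in range(n_times)]
    scan_int: List[List[float]] = [[] for _ in range(n_times)]
    for e in members:
        sim = sim_of[e.identifier]
        profile = sim.apex * _gaussian(times, sim.rt, params.peak_sigma)
        visible = profile > 10.0
        jitter = rng.uniform(0.99, 1.01, size=int(visible.sum()))
        profile[visible] *= jitter
        if sim.violation == "snr":
            # elevated noisy baseline in this channel, clean under the peak
            sigma_n = sim.apex / 2.5
            outside = np.abs(times - sim.rt) > 4.0 * params.peak_sigma
            noise = sigma_n * (3.0 + np.clip(
                rng.standard_normal(n_times), -2.2, 2.2))
            profile[outside] += noise[outside]
            profile[~outside] += 3.0 * sigma_n
            visible = profile > 10.0
        for idx in np.nonzero(visible)[0]:
            scan_mz[idx].append(obs_mz[e.identifier])
            scan_int[idx].append(float(profile[idx]))

    ms2_schedule: Dict[int, List[CompoundEntry]] = {}
    for e in members:
        sim = sim_of[e.identifier]
        if sim.violation == "ms2_present":
            continue
        apex_idx = int(np.argmin(np.abs(times - sim.rt)))
        if sim.violation == "rt_shift":
            shift = int(round(0.7 / params.ms1_interval))
            apex_idx = min(apex_idx + shift, n_times - 1)
        n_ms2 = min(params.ms2_per_compound, 3)
        for k in range(n_ms2):
            idx = apex_idx + (k - n_ms2 // 2)
            if 0 <= idx < n_times:
                ms2_schedule.setdefault(idx, []).append(e)

    frag_key = f"{ce:g}"
    scans: List[Scan] = []
    for i, t in enumerate(times):
        mz_list = scan_mz[i]
        int_list = scan_int[i]
        n_noise = int(rng.poisson(params.noise_peaks_per_scan))
        if n_noise:
            noise_mz = rng.uniform(60.0, 900.0, size=n_noise)
            noise_int = rng.exponential(params.noise_level, size=n_noise)
            mz_list.extend(noise_mz.tolist())
            int_list.extend(np.maximum(noise_int, 1.0).tolist())
        scans.append(Scan(
            ms_level=1, retention_time=float(t),
            mz=np.array(mz_list), intensity=np.array(int_list),
            polarity=mode,
        ))
        for e in ms2_schedule.get(i, ()):
            sim = sim_of[e.identifier]
            frags = truth.fragments.get(e.identifier, {}).get(frag_key, [])
            if not frags:
                continue
            frag_mz = []
            frag_int = []
            prec_theo = e.ion_mz(adduct)
            base = max(sim.apex * 0.5, 1.0)
            center = 1.0 - (ce / 100.0)  # favoured m/z fraction of precursor
            for formula in frags:
                theo = ion_mz_of_formula(
                    chem.parse_formula(formula),
                    +1 if adduct.charge > 0 else -1)
                frac = theo / prec_theo
                weight = np.exp(-((frac - center) / 0.45) ** 2)
                inten = base * weight * float(rng.uniform(0.3, 1.0))
                frag_mz.append(_apply_error(theo, params))
                frag_int.append(max(inten, 1.0))
            # guarantee the planted base peak carries the full intensity
            frag_int[int(np.argmax(frag_int))] = base
            scans.append(Scan(
                ms_level=2,
                retention_time=float(t) + params.ms1_interval * 0.25,
                mz=np.array(frag_mz), intensity=np.array(frag_int),
                polarity=mode,
                precursor_mz=obs_mz[e.identifier],
                isolation_window_width=params.isolation_window,
                collision_energy=ce,
            ))
    return Run(scans=scans, mix=mix, mode=mode, collision_energy=ce)


# ---------------------------------------------------------------------------
# Canned scenarios


def default_settings() -> Settings:
    return Settings(
        authors="Synthetic Fixture Consortium",
        license="CC BY",
        instrument="Q Exactive HF Thermo Scientific",
        instrument_type="LC-ESI-QFT",
        ionization="ESI",
        contributor="LCSB",
        accession_prefix="LU",
        fragmentation_mode="HCD",
        column_name="Acquity UPLC BEH C18 1.7um 2.1x150mm",
        flow_gradient="90/10 at 0 min, 0/100 at 15 min",
    )


def two_mix_isobar_scenario(params: Optional[SimParams] = None
                  ) -> Tuple[List[CompoundEntry], MixDesign, GroundTruth,
                             Dict[Tuple[str, str, float], Run]]:
    """Two-mix worked isobar example.

    Mix "503" contains only the benzofuran amine (RT 12.3 min); mix "508"
    contains both it and the same-formula acetamide (RT 14.4 min), so both
    EIC peaks appear at ion m/z 164.1070 in mix 508 and the solo mix
    anchors the amine's identity.
    """
    params = params or SimParams()
    amine, acetamide = _isobar_pair(0, 1)
    entries = [amine, acetamide]
    design = MixDesign(mixes={
        "503": {amine.identifier},
        "508": {amine.identifier, acetamide.identifier},
    })
    truth = GroundTruth()
    truth.compounds[amine.identifier] = CompoundSim(rt=12.3, apex=8.0e5)
    truth.compounds[acetamide.identifier] = CompoundSim(rt=14.4, apex=1.2e6)
    for mix in design.mixes:
        truth.peak_map[mix] = sorted(
            (truth.compounds[c].rt, c) for c in design.compounds_in(mix))
    truth.fragments = plant_fragments(entries, params)
    runs = {}
    for mix in sorted(design.mixes):
        mix_entries = [e for e in entries
                       if e.identifier in design.compounds_in(mix)]
        for ce in params.ce_levels[:2]:
            runs[(mix, "+", ce)] = simulate_run(
                mix_entries, mix, "+", ce, params, truth)
    return entries, design, truth, runs


def write_dataset(outdir, entries: Sequence[CompoundEntry],
                  design: MixDesign, truth: GroundTruth, params: SimParams,
                  modes: Sequence[str] = ("+",),
                  ce_levels: Optional[Sequence[float]] = None,
                  settings: Optional[Settings] = None) -> Dict[str, str]:
    """Write a complete input dataset: mzML runs, compound list CSV, setID
    CSV, settings INI and the ground-truth JSON.  Returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ce_levels = list(ce_levels if ce_levels is not None
                     else params.ce_levels)
    by_id = {e.identifier: e for e in entries}
    paths: Dict[str, str] = {}
    mzml_dir = outdir / "mzml"
    mzml_dir.mkdir(exist_ok=True)
    for mix in sorted(design.mixes):
        mix_entries = [by_id[c] for c in sorted(design.compounds_in(mix))]
        for mode in modes:
            for ce in ce_levels:
                run = simulate_run(mix_entries, mix, mode, ce, params, truth)
                tag = "pos" if mode == "+" else "neg"
                path = mzml_dir / f"mix{mix}_{tag}_ce{ce:g}.mzML"
                write_run(run, path)
                paths[f"run:{mix}:{mode}:{ce:g}"] = str(path)
    import csv

    cmp_path = outdir / "compounds.csv"
    with open(cmp_path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["Identifier", "Name", "SMILES"])
        for e in sorted(entries, key=lambda e: e.identifier):
            writer.writerow([e.identifier, e.name, e.ms_ready_smiles])
    paths["compounds"] = str(cmp_path)
    setid_path = outdir / "setid.csv"
    with open(setid_path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["Identifier", "Mix"])
        for mix in sorted(design.mixes):
            for cid in sorted(design.compounds_in(mix)):
                writer.writerow([cid, mix])
    paths["setid"] = str(setid_path)
    settings_path = write_settings(settings or default_settings(),
                                   outdir / "settings.ini")
    paths["settings"] = str(settings_path)
    truth_path = outdir / "ground_truth.json"
    truth_path.write_text(truth.to_json())
    paths["ground_truth"] = str(truth_path)
    return paths
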