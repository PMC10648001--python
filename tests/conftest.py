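"""Shared fixtures: small synthetic datasets with known ground truth."""

import numpy as np
import pytest

from mixlib import fixtures
from mixlib.msio import Run, Scan


@pytest.fixture(scope="session")
def isobar_example():
    """The two-mix worked isobar example (compounds, design, truth, runs)."""
    return fixtures.two_mix_isobar_scenario()


@pytest.fixture(scope="session")
def qc_mix():
    """A 50-compound mix with planted QC violations.

    Returns (entries, design, truth, run, violations): ten compounds carry
    exactly one planted violation each; the rest are clean.
    """
    params = fixtures.SimParams(seed=7)
    entries, design = fixtures.generate_design(
        sizes={"qc": 50}, replicate_plan={}, seed=7)
    ids = sorted(design.compounds_in("qc"))
    violations = {
        ids[0]: "intensity", ids[1]: "intensity", ids[2]: "intensity",
        ids[10]: "snr", ids[11]: "snr",
        ids[20]: "ms2_present", ids[21]: "ms2_present",
        ids[30]: "rt_shift", ids[31]: "rt_shift", ids[32]: "rt_shift",
    }
    truth = fixtures.assign_ground_truth(
        entries, design, params, violations=violations)
    truth.fragments = fixtures.plant_fragments(entries, params)
    run = fixtures.simulate_run(entries, "qc", "+", 15.0, params, truth)
    return entries, design, truth, run, violations


@pytest.fixture(scope="session")
def three_mix_dataset(tmp_path_factory):
    """A clean 3-mix dataset written to disk (no ambiguous isobars, all
    compounds above thresholds), plus its generation inputs."""
    root = tmp_path_factory.mktemp("three_mix")
    params = fixtures.SimParams(seed=11)
    entries, design = fixtures.generate_design(
        sizes={"601": 8, "602": 8, "603": 8}, replicate_plan={}, seed=11)
    truth = fixtures.assign_ground_truth(entries, design, params)
    truth.fragments = fixtures.plant_fragments(entries, params)
    paths = fixtures.write_dataset(
        root / "data", entries, design, truth, params,
        ce_levels=params.ce_levels[:2])
    return {"root": root, "params": params, "entries": entries,
            "design": design, "truth": truth, "paths": paths}


def make_run(peak_rts, apexes, target_mz=164.1070, sigma=0.05,
             interval=0.02, rt_max=16.0, ms2_at=None, noise=None,
             seed=0, polarity="+"):
    """Hand-built run: Gaussian EIC peaks at given RTs plus optional MS2
    scans and baseline noise; independent of the fixtures module."""
    rng = np.random.default_rng(seed)
    times = np.arange(0.2, rt_max, interval)
    scans = []
    ms2_at = list(ms2_at or [])
    for t in times:
        height = sum(a * np.exp(-0.5 * ((t - rt) / sigma) ** 2)
                     for rt, a in zip(peak_rts, apexes))
        if noise:
            height += abs(rng.normal(0.0, noise))
        mz = [target_mz] if height > 1.0 else []
        inten = [height] if height > 1.0 else []
        scans.append(Scan(1, float(t), np.array(mz), np.array(inten),
                          polarity=polarity))
        for (rt2, prec) in list(ms2_at):
            if abs(t - rt2) < interval / 2:
                scans.append(Scan(
                    2, float(t) + interval / 4,
                    np.array([91.0542, prec]), np.array([5e4, 2e5]),
                    polarity=polarity, precursor_mz=prec,
                    isolation_window_width=1.0, collision_energy=30.0))
    return Run(scans=scans, mix="test", mode=polarity, collision_energy=30.0)
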