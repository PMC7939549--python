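#!/usr/bin/env python
"""Generate every synthetic dataset the downstream analyses consume.

Writes image stacks, traces, correlation curves and trajectories (with
ground-truth JSON sidecars) under scratch/data/, and a manifest of what was
generated. Later analysis scripts read these files through the package's own
readers, exercising the full file-format round trip.
"""

import sys
from pathlib import Path

import numpy as np

from lamindyn import io as lio
from lamindyn import synthetic as syn
from lamindyn.fcs import FCSModelParams

SEED = 20260922
DATA = Path(__file__).resolve().parents[1] / "scratch" / "data"


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    # --- nucleus fields for N/P ratio + cell-cycle staging (50 nuclei) ---
    for i in range(10):
        cfg = syn.SyntheticNucleusConfig(
            n_nuclei=5, nucleus_radius=4.0, noise_sd=5.0,
            seed=int(rng.integers(2**31)))
        image, truth = syn.gen_nucleus_image(cfg)
        lio.write_tiff(DATA / f"nuclei_{i:02d}.tif", image)
        lio.write_json(DATA / f"nuclei_{i:02d}_truth.json", {
            "true_np_ratio": truth.true_np_ratio,
            "true_cell_cycle_label": truth.true_cell_cycle_label,
            "dna_totals": truth.extra["dna_totals"]})

    # --- post-mitotic redistribution time-lapse, N/P decaying 1 -> 0.25 ---
    curve = np.geomspace(1.0, 0.25, 8)
    cfg = syn.SyntheticNucleusConfig(noise_sd=2.0, seed=int(rng.integers(2**31)))
    frames, _ = syn.gen_timelapse(cfg, curve)
    for t, frame in enumerate(frames):
        lio.write_tiff(DATA / f"timelapse_t{t}.tif", frame)
    lio.write_json(DATA / "timelapse_truth.json", {"ratio_curve": curve})

    # --- CP cohorts emulating wild-type vs LAP2a-knockout mobility ---
    for name, lo, hi in (("wt", 0.10, 0.40), ("ko", 0.30, 0.60)):
        truths = []
        for j in range(60):
            f = float(rng.uniform(lo, hi))
            ccfg = syn.SyntheticCPConfig(f_immobile_true=f, noise_sd=0.02,
                                         seed=int(rng.integers(2**31)))
            trace, _ = syn.gen_cp_trace(ccfg)
            lio.write_trace_csv(DATA / f"cp_{name}_{j:02d}.csv", trace)
            truths.append(f)
        lio.write_json(DATA / f"cp_{name}_truth.json",
                       {"true_f_immobile": truths})

    # --- FCS curves: two diffusing species, WT-like and KO-like kinetics ---
    # KO complexes are lighter (no LAP2a) hence diffuse faster: shorter taus
    for name, taus in (("wt", (1.2e-3, 2.4e-2)), ("ko", (1.0e-3, 2.0e-2))):
        params = FCSModelParams(rho=[0.6, 0.4], tau_diff=list(taus),
                                T=[0.15], tau_trip=[5e-6], G_inf=0.0)
        for j in range(10):
            c = syn.gen_fcs_curve(params, noise_frac=0.01,
                                  seed=int(rng.integers(2**31)))
            lio.write_curve_csv(DATA / f"fcs_{name}_{j:02d}.csv", c)
        lio.write_json(DATA / f"fcs_{name}_truth.json", {
            "rho": params.rho, "tau_diff_s": params.tau_diff,
            "T": params.T, "tau_trip_s": params.tau_trip})

    # --- telomere trajectories: 4 genotype-like motion regimes ---
    regimes = {
        "wt": dict(motion_model="anomalous", D_true=4e-4, alpha_true=0.6),
        "lap2a_ko": dict(motion_model="anomalous", D_true=2e-4,
                         alpha_true=0.5),
        "lmna_ko": dict(motion_model="free", D_true=8e-4, alpha_true=1.0),
        "dko": dict(motion_model="free", D_true=8e-4, alpha_true=1.0),
    }
    for name, kw in regimes.items():
        trajs = []
        for s in range(3):  # 3 nuclei per genotype
            cfg = syn.SyntheticTrajectoryConfig(
                n_telomeres=40, drift_velocity=0.002, rotation_rate=0.0005,
                localization_noise_sd=0.01,
                seed=int(rng.integers(2**31)), **kw)
            nuc, _ = syn.gen_trajectories(cfg)
            for tr in nuc:
                tr.nucleus_id = s
            trajs += nuc
        lio.write_trajectories_csv(DATA / f"telomeres_{name}.csv", trajs)
    lio.write_json(DATA / "telomeres_truth.json", regimes)

    # --- intranuclear structure fixture ---
    spots = [((0.0, 0.0), 0.5), ((2.0, 0.0), 0.4), ((0.0, 2.0), 0.6),
             ((-2.0, -2.0), 0.3), ((1.5, -1.5), 0.5),
             ((0.0, 4.4), 0.2), ((-4.4, 0.0), 0.2)]
    scfg = syn.SyntheticNucleusConfig(noise_sd=0.0,
                                      seed=int(rng.integers(2**31)))
    simage, struth = syn.gen_structure_image(spots, scfg)
    lio.write_tiff(DATA / "structures.tif", simage)
    lio.write_json(DATA / "structures_truth.json",
                   {"true_structure_count": struth.true_structure_count,
                    "spots": struth.extra["spots"]})

    lio.write_manifest(DATA / "manifest.json", {"script": "01_simulate"},
                       SEED)
    print(f"simulated datasets written to {DATA}")


if __name__ == "__main__":
    sys.exit(main())
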