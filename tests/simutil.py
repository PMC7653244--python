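"""Shared simulator test helpers (tracer diffusion, trace construction)."""

import numpy as np

from memfluid import memsim


def tracer_msd_slope(n_particles=2000, n_steps=10_000, seed=0):
    """Mean-squared-displacement slope of non-reacting tracers.

    All reaction channels are switched off so receptors are pure Brownian
    tracers; per-step displacements are unwrapped with the minimum-image
    convention (valid because step RMS << box).  Returns (slope, 4*D) where
    slope is the through-origin regression of MSD(t) on t at 10 checkpoints.
    """
    cfg = memsim.SimConfig(
        n_receptors=n_particles,
        n_scaffolds=1,
        n_functionals=1,
        n_inhibitors=1,
        p_ligand_on=0.0,
        p_basal=0.0,
        k_feedback=0.0,
        protocol="resting",
        seed=seed,
    )
    state = memsim.init(cfg)
    L = cfg.box_size
    disp = np.zeros_like(state.r_pos)
    checkpoints = []
    prev = state.r_pos.copy()
    for i in range(n_steps):
        memsim.step(state, cfg)
        d = state.r_pos - prev
        d -= L * np.round(d / L)
        disp += d
        prev = state.r_pos.copy()
        if (i + 1) % (n_steps // 10) == 0:
            msd = float(np.mean(np.sum(disp**2, axis=1)))
            checkpoints.append(((i + 1) * cfg.dt, msd))
    t = np.array([c[0] for c in checkpoints])
    msd = np.array([c[1] for c in checkpoints])
    slope = float(np.sum(msd * t) / np.sum(t * t))
    return slope, 4.0 * cfg.diffusivity


def make_trace(output_signal=None, t3_frac=None, config=None, dt=1e-3):
    """Build a SimTrace from prescribed signal arrays (for metric tests)."""
    if config is None:
        config = memsim.SimConfig()
    n = len(output_signal) if output_signal is not None else len(t3_frac)
    times = (np.arange(n) + 1) * dt
    zeros = np.zeros(n)
    return memsim.SimTrace(
        times=times,
        t1_frac=zeros.copy(),
        t2_frac=zeros.copy(),
        t3_frac=zeros.copy() if t3_frac is None else np.asarray(t3_frac, float),
        receptor_activation=zeros.copy(),
        output_counts=zeros.copy(),
        output_signal=zeros.copy() if output_signal is None else np.asarray(output_signal, float),
        config=config,
        seed=config.seed,
    )
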