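"""Two-stage Gibbs-EM training for treeLFA.

Each EM cycle runs an E-step (19 warm-started Gibbs sweeps by default,
then opt_N consecutive sweeps whose hidden-variable samples are kept)
followed by an M-step that re-optimizes the Dirichlet hyperparameter
alpha by a fixed-point iteration on the Dirichlet-multinomial
log-likelihood, with every entry floored at 0.01 to avoid degeneration.
Stage 1 (typically opt_N_1=1) does many cheap cycles; stage 2
(opt_N_2=10 recommended) refines alpha from more posterior samples.
Checkpoints are written every 50 cycles in stage 1 and every 5 in
stage 2 and permit bit-exact resumption.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import digamma

from .io_formats import (
    DiagnosisMatrix,
    RunConfig,
    RunParamError,
    TreeStructure,
    validate_run_params,
)
from .model_core import (
    ALPHA_FLOOR,
    Hyperparams,
    ModelState,
    init_state,
    priors_for_data,
)
from .gibbs_sampler import log10_joint, sweep


@dataclass
class EMResult:
    """Final state and optimized alpha after Gibbs-EM training."""

    state: ModelState
    alpha: np.ndarray
    L_all: list[float] = field(default_factory=list)
    stage_boundary: int = 0  # number of stage-1 cycles in L_all


def mstep_alpha(
    Z_sum_samples: Sequence[np.ndarray],
    alpha: np.ndarray,
    S: int,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Fixed-point optimization of the Dirichlet-multinomial alpha.

    Maximizes the expected log-likelihood of the topic-assignment counts
    under Dirichlet(alpha), the expectation taken as the average over
    the provided Z_sum samples. The standard digamma fixed point

        alpha_k <- alpha_k * E[sum_d psi(n_dk + alpha_k) - D psi(alpha_k)]
                           / (D (psi(S + A) - psi(A)))

    (A = sum alpha; every individual has exactly S assignments) is
    iterated to relative change < tol, and each entry is floored at
    0.01, so a topic with no counts anywhere returns exactly the floor.
    """
    if len(Z_sum_samples) == 0:
        raise ValueError("at least one Z_sum sample is required")
    alpha = np.asarray(alpha, dtype=float).copy()
    K = alpha.shape[0]
    D = Z_sum_samples[0].shape[0]
    # average histogram of counts per topic: H[k, n] = mean #individuals
    # with n assignments to topic k; digamma is then evaluated on a grid.
    H = np.zeros((K, S + 1))
    for zs in Z_sum_samples:
        if zs.shape != (D, K):
            raise ValueError("Z_sum samples must share one shape")
        for k in range(K):
            H[k] += np.bincount(zs[:, k], minlength=S + 1)
    H /= len(Z_sum_samples)
    grid = np.arange(S + 1)
    for _ in range(max_iter):
        A = alpha.sum()
        num = (H * digamma(grid[None, :] + alpha[:, None])).sum(axis=1) - D * digamma(alpha)
        den = D * (digamma(S + A) - digamma(A))
        new = np.maximum(alpha * num / den, ALPHA_FLOOR)
        if np.max(np.abs(new - alpha) / np.maximum(alpha, 1e-300)) < tol:
            alpha = new
            break
        alpha = new
    return alpha


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def config_digest(
    data: DiagnosisMatrix,
    tree: TreeStructure,
    K: int,
    alpha0: np.ndarray,
    burn_in: int,
    opt_N_1: int,
    opt_N_2: int,
    seed: int,
) -> str:
    """Digest of the inputs a checkpoint must match before resuming.

    Cycle counts are deliberately excluded so that a training run can be
    extended (continued) from its last checkpoint.
    """
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(data.values).tobytes())
    h.update("\x00".join(data.codes).encode())
    h.update(json.dumps(sorted(tree.parent.items())).encode())
    h.update(np.asarray(alpha0, dtype=float).tobytes())
    h.update(json.dumps([K, burn_in, opt_N_1, opt_N_2, seed]).encode())
    return h.hexdigest()


def save_checkpoint(
    directory: str | Path,
    state: ModelState,
    alpha: np.ndarray,
    cycle_index: int,
    rng: np.random.Generator,
    digest: str,
    L_all: Sequence[float],
) -> None:
    """Write state arrays (.npy) plus a JSON manifest with alpha, cycle
    index, RNG state and the config digest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, arr in (
        ("Phi", state.Phi),
        ("I", state.I),
        ("Z", state.Z),
        ("Z_sum", state.Z_sum),
    ):
        np.save(directory / f"{name}.npy", arr)
    manifest = {
        "alpha": np.asarray(alpha, dtype=float).tolist(),
        "rho": state.rho.tolist(),
        "cycle_index": int(cycle_index),
        "rng_state": rng.bit_generator.state,
        "digest": digest,
        "L_all": list(map(float, L_all)),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest))


def resume(
    checkpoint_dir: str | Path, digest: str | None = None
) -> tuple[ModelState, np.ndarray, int, np.random.Generator, list[float]]:
    """Load a checkpoint; verify the config digest when one is supplied."""
    directory = Path(checkpoint_dir)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no checkpoint manifest in {directory}")
    manifest = json.loads(manifest_path.read_text())
    if digest is not None and manifest["digest"] != digest:
        raise RunParamError(
            "checkpoint digest mismatch: the checkpoint was written for "
            "different data or configuration"
        )
    state = ModelState(
        Phi=np.load(directory / "Phi.npy"),
        I=np.load(directory / "I.npy"),
        rho=np.asarray(manifest["rho"], dtype=float),
        Z=np.load(directory / "Z.npy"),
        Z_sum=np.load(directory / "Z_sum.npy"),
    )
    state.check()
    rng = np.random.default_rng()
    rng.bit_generator.state = manifest["rng_state"]
    alpha = np.asarray(manifest["alpha"], dtype=float)
    return state, alpha, int(manifest["cycle_index"]), rng, list(manifest["L_all"])


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

CHECKPOINT_EVERY_STAGE1 = 50
CHECKPOINT_EVERY_STAGE2 = 5


def gibbs_em_train(
    data: DiagnosisMatrix,
    tree: TreeStructure,
    K: int,
    alpha0: np.ndarray,
    cycle_1: int,
    cycle_2: int,
    burn_in: int = 19,
    opt_N_1: int = 1,
    opt_N_2: int = 10,
    seed: int = 0,
    init: tuple[ModelState, np.ndarray] | None = None,
    checkpoint_dir: str | Path | None = None,
    resume_from: str | Path | None = None,
) -> EMResult:
    """Two-stage Gibbs-EM training.

    Per EM cycle the E-step runs `burn_in` warm-started sweeps and then
    collects opt_N consecutive sweeps' Z_sum samples; the M-step updates
    alpha from them. One log10-joint value per cycle goes into L_all.
    `init` continues training from a previous result's (state, alpha);
    `resume_from` restores a checkpoint bit-exactly (RNG state included).
    """
    alpha0 = np.asarray(alpha0, dtype=float)
    cfg = RunConfig(
        K=K, alpha0=alpha0, opt_N_1=opt_N_1, cycle_1=cycle_1,
        opt_N_2=opt_N_2, cycle_2=cycle_2, burn_in=burn_in,
    )
    violations = validate_run_params(cfg)
    if violations:
        raise RunParamError("; ".join(map(str, violations)))
    if opt_N_1 < 1 or opt_N_2 < 1:
        raise RunParamError("opt_N_1 and opt_N_2 must be at least 1")

    digest = config_digest(data, tree, K, alpha0, burn_in, opt_N_1, opt_N_2, seed)
    priors = priors_for_data(data)
    tree.align_terminals(data.codes)

    L_all: list[float] = []
    start_cycle = 0
    if resume_from is not None:
        state, alpha, start_cycle, rng, L_all = resume(resume_from, digest)
        if state.K != K or state.S != data.S or state.D != data.D:
            raise RunParamError("checkpoint state shape does not match inputs")
    else:
        rng = np.random.default_rng(seed)
        if init is not None:
            state, alpha = init[0].copy(), np.asarray(init[1], dtype=float).copy()
            if state.K != K or len(alpha) != K:
                raise RunParamError("init state/alpha shapes do not match K")
            if state.S != data.S or state.D != data.D:
                raise RunParamError("init state shape does not match the data")
        else:
            state = init_state(data, tree, K, rng)
            alpha = alpha0.copy()

    total = cycle_1 + cycle_2
    hyper = Hyperparams(alpha=alpha, phi_priors=priors)
    for c in range(start_cycle + 1, total + 1):
        stage1 = c <= cycle_1
        opt_N = opt_N_1 if stage1 else opt_N_2
        hyper.alpha = alpha
        for _ in range(burn_in):
            sweep(state, data, tree, hyper, rng)
        samples = []
        for _ in range(opt_N):
            sweep(state, data, tree, hyper, rng)
            samples.append(state.Z_sum.copy())
        alpha = mstep_alpha(samples, alpha, data.S)
        hyper.alpha = alpha
        L_all.append(log10_joint(state, data, hyper, tree))
        if checkpoint_dir is not None:
            every = CHECKPOINT_EVERY_STAGE1 if stage1 else CHECKPOINT_EVERY_STAGE2
            stage_cycle = c if stage1 else c - cycle_1
            if stage_cycle % every == 0 or c == total:
                save_checkpoint(checkpoint_dir, state, alpha, c, rng, digest, L_all)
    return EMResult(state=state, alpha=alpha, L_all=L_all, stage_boundary=min(cycle_1, total))
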