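"""Independent brute-force reference implementation of the scoring path.

Deliberately written from first principles with raw numpy SVD and explicit
Procrustes algebra (no sklearn, no scipy.linalg.orthogonal_procrustes) so it
can serve as an oracle for the package's scoring pipeline on small problems.
"""

from __future__ import annotations

import numpy as np


def _canon(vt: np.ndarray) -> np.ndarray:
    out = vt.copy()
    for i, row in enumerate(out):
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            out[i] = -row
    return out


def _procrustes_align(config, reference):
    mu_c = config.mean(axis=0)
    mu_r = reference.mean(axis=0)
    a = config - mu_c
    b = reference - mu_r
    u, _, vt = np.linalg.svd(a.T @ b)
    rot = u @ vt
    return a @ rot + mu_r


def brute_force_model(control_trials, variance_threshold=0.90, beta=25.0):
    """Fit the reference from a list of T x d control coordinate matrices."""
    stacked = np.vstack(control_trials)
    mu = stacked.mean(axis=0)
    xc = stacked - mu
    _, svals, vt = np.linalg.svd(xc, full_matrices=False)
    evr = svals**2 / np.sum(svals**2)
    cum = np.cumsum(evr)
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    k = min(k, len(evr))
    basis = _canon(vt[:k])
    weights = evr[:k] / evr[:k].sum()
    projections = [(t - mu) @ basis.T for t in control_trials]
    reference = np.mean(projections, axis=0)
    ref_profile = reference @ weights

    def profile(trial):
        aligned = _procrustes_align((trial - mu) @ basis.T, reference)
        return aligned @ weights

    deviations = [np.mean(np.abs(profile(t) - ref_profile)) for t in control_trials]
    d_cal = float(np.mean(deviations))
    return dict(
        mu=mu, basis=basis, weights=weights, evr=evr[:k],
        reference=reference, ref_profile=ref_profile, d_cal=d_cal,
        beta=beta, profile=profile,
    )


def brute_force_score(model: dict, trial: np.ndarray) -> float:
    d = float(np.mean(np.abs(model["profile"](trial) - model["ref_profile"])))
    return 100.0 * (1.0 - d / (model["beta"] * model["d_cal"]))
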