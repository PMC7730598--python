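import numpy as np


def _profiled_grid_search(tau, q, w_eff, pivot, n_stages, points):
    """Exhaustive shrinking-grid search over all activations except ``pivot``,
    which is minimized exactly by its 1-D closed form (with bound clipping)
    at every grid point.  Every evaluation is of the true objective."""
    q_p = q[pivot]
    q_o = np.delete(q, pivot)
    n_outer = len(q_o)

    def objective_profiled(outer_nd):
        c = tau - outer_nd @ q_o
        a_p = np.clip(w_eff * q_p * c / (1.0 + w_eff * q_p**2), 0.0, 1.0)
        resid = c - q_p * a_p
        return np.sum(outer_nd**2, axis=1) + a_p**2 + w_eff * resid**2

    if n_outer == 0:
        return float(objective_profiled(np.zeros((1, 0)))[0])

    lo = np.zeros(n_outer)
    hi = np.ones(n_outer)
    best = np.inf
    for _ in range(n_stages):
        axes = [np.linspace(lo[i], hi[i], points) for i in range(n_outer)]
        mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        mesh = mesh.reshape(-1, n_outer)
        values = objective_profiled(mesh)
        k = int(np.argmin(values))
        best = min(best, float(values[k]))
        step = (hi - lo) / (points - 1)
        lo = np.clip(mesh[k] - 3 * step, 0.0, 1.0)
        hi = np.clip(mesh[k] + 3 * step, 0.0, 1.0)
    return best


def grid_search_activation_objective(tau, gains, weight, tau0=1.0,
                                     n_stages=8, points=41):
    """Independent brute-force oracle for the static-optimization program

        min  sum(a_i^2) + W * (tau - q . a)^2,   0 <= a_i <= 1,

    with W = weight / tau0^2.  The reserve-penalty term makes the objective
    extremely anisotropic (a narrow valley along the moment-balance plane),
    so a naive box grid cannot localize the minimum.  Instead, one
    activation at a time is minimized exactly by its 1-D closed form while
    the others are searched exhaustively on a shrinking grid; the search is
    repeated with every activation as the profiled one and the best value
    kept (whichever pivot is interior-active at the optimum yields a
    well-conditioned reduced problem).  No solver machinery is shared with
    the implementation.  Returns the best objective value found.
    """
    q = np.asarray(gains, dtype=float)
    w_eff = weight / tau0**2
    return min(
        _profiled_grid_search(tau, q, w_eff, pivot, n_stages, points)
        for pivot in range(len(q))
    )
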