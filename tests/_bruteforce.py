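"""Independent brute-force oracle used to validate the box-constrained solver."""

import numpy as np


def brute_force_objective(C, X, step=0.01):
    """Exhaustive grid search of ||X - C^T w||^2 over w in {0, step, ..., 1}^K."""
    K = C.shape[0]
    grid = np.arange(0.0, 1.0 + step / 2, step)
    G = C @ C.T
    c = C @ X
    best = np.inf
    mesh = np.stack(np.meshgrid(*([grid] * K), indexing="ij"), axis=-1).reshape(-1, K)
    for chunk in np.array_split(mesh, max(1, mesh.shape[0] // 200_000)):
        vals = np.einsum("ij,jk,ik->i", chunk, G, chunk) - 2.0 * chunk @ c
        best = min(best, vals.min())
    return best + X @ X
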