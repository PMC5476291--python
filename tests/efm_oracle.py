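"""Independent brute-force elementary-mode oracle for small networks.

Enumerates support-minimal flux vectors of {v : S_int v = 0, v_irrev >= 0}
by exhaustive search over support subsets: a support is elementary iff the
kernel of the restricted matrix is one-dimensional, admits a sign-feasible
representative with full support, and no proper sub-support does.  Used
only as a cross-check; independent of the package's double-description
enumeration.
"""

from itertools import combinations

import numpy as np
from scipy.linalg import null_space


def brute_force_modes(S, reversible, tol=1e-9):
    """All elementary modes of S (internal metabolites x reactions).

    ``reversible`` is a boolean sequence per reaction.  Returns a list of
    flux vectors normalized to unit maximum absolute flux.
    """
    n = S.shape[1]
    elementary = []
    supports = []
    for size in range(1, n + 1):
        for support in combinations(range(n), size):
            if any(set(s) < set(support) for s in supports):
                continue
            sub = S[:, support]
            kernel = null_space(sub, rcond=1e-10)
            if kernel.shape[1] != 1:
                continue
            v = kernel[:, 0]
            if np.min(np.abs(v)) <= tol * np.max(np.abs(v)):
                continue  # support not full: a smaller support exists
            # orient: irreversible reactions must be non-negative; a mode
            # over reversible reactions only equals its negation and gets a
            # canonical orientation (positive on its first reaction)
            irrev = [j for j, r in enumerate(support) if not reversible[r]]
            if irrev:
                signs = np.sign(v[irrev])
                if np.all(signs > 0):
                    pass
                elif np.all(signs < 0):
                    v = -v
                else:
                    continue
            elif v[0] < 0:
                v = -v
            full = np.zeros(n)
            full[list(support)] = v / np.max(np.abs(v))
            elementary.append(full)
            supports.append(support)
    return elementary


def modes_as_set(vectors, reaction_ids, tol=1e-7):
    """Canonical frozenset representation (rounded, scale-normalized)."""
    out = set()
    for v in vectors:
        scale = np.max(np.abs(v))
        canon = tuple(
            (reaction_ids[j], round(v[j] / scale, 6))
            for j in range(len(v))
            if abs(v[j] / scale) > tol
        )
        out.add(canon)
    return out
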