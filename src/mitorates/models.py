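"""Amino-acid substitution models (general time-reversible form).

A model is an exchangeability matrix ``S`` (symmetric, non-negative
off-diagonal) plus equilibrium frequencies ``pi``; the rate matrix is
``Q = S @ diag(pi)`` with the diagonal set so rows sum to zero, scaled so the
expected number of substitutions per site per unit branch length is 1.
Across-site rate heterogeneity uses a discrete-gamma with ``n_categories``
equal-probability categories of shape ``alpha`` (see
:func:`mitorates.likelihood.discretize_gamma`).

The built-in model is the Poisson (equal-exchangeability) model; empirical
matrices (WAG/LG-style) can be loaded from PAML-format ``.dat`` files.
"""

from __future__ import annotations

import numpy as np

from .alignment import AA_LETTERS

__all__ = ["SubstitutionModel", "poisson_model", "read_paml_matrix"]

N_STATES = 20


class SubstitutionModel:
    def __init__(
        self,
        name: str,
        exchangeabilities: np.ndarray,
        frequencies: np.ndarray,
        alpha: float = 1.0,
        n_categories: int = 4,
    ):
        S = np.asarray(exchangeabilities, float)
        pi = np.asarray(frequencies, float)
        if S.shape != (N_STATES, N_STATES):
            raise ValueError("exchangeability matrix must be 20x20")
        if not np.allclose(S, S.T):
            raise ValueError("exchangeability matrix must be symmetric")
        off = S[~np.eye(N_STATES, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("exchangeabilities must be non-negative")
        if pi.shape != (N_STATES,) or np.any(pi < 0):
            raise ValueError("frequencies must be 20 non-negative values")
        if abs(pi.sum() - 1.0) > 1e-6:
            raise ValueError(f"frequencies must sum to 1 (got {pi.sum():.8f})")
        if not alpha > 0:
            raise ValueError("gamma shape alpha must be > 0")
        if n_categories < 1:
            raise ValueError("n_categories must be >= 1")
        self.name = name
        self.exchangeabilities = S
        self.frequencies = pi / pi.sum()  # exact normalisation
        self.alpha = float(alpha)
        self.n_categories = int(n_categories)

        Q = S * self.frequencies[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.dot(self.frequencies, np.diag(Q))
        if mu <= 0:
            raise ValueError("degenerate rate matrix: zero total rate")
        Q /= mu
        self.Q = Q
        # reversible Q diagonalised via the symmetrised matrix
        # B = diag(sqrt(pi)) Q diag(1/sqrt(pi)); P(t) = R V exp(Lt) V' R^-1
        sq = np.sqrt(np.maximum(self.frequencies, 1e-300))
        B = (sq[:, None] * Q) / sq[None, :]
        lam, V = np.linalg.eigh((B + B.T) / 2.0)
        self._lam = lam
        self._left = V / sq[:, None]        # diag(1/sqrt(pi)) V
        self._right = (V * sq[:, None]).T   # V' diag(sqrt(pi))

    # -------------------------------------------------------------- variants
    def with_frequencies(self, frequencies: np.ndarray) -> "SubstitutionModel":
        return SubstitutionModel(
            self.name, self.exchangeabilities, frequencies, self.alpha,
            self.n_categories,
        )

    def with_alpha(self, alpha: float) -> "SubstitutionModel":
        return SubstitutionModel(
            self.name, self.exchangeabilities, self.frequencies, alpha,
            self.n_categories,
        )

    # ------------------------------------------------------------ transitions
    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1."""
        if t < 0 or not np.isfinite(t):
            raise ValueError(f"branch length must be finite and >= 0, got {t}")
        P = (self._left * np.exp(self._lam * t)) @ self._right
        np.maximum(P, 0.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_matrices(self, t: float, rates: np.ndarray) -> np.ndarray:
        """Stack of P(t * r) for each category rate r: shape (k, 20, 20).

        Negative round-off entries are clipped at 0; rows then sum to 1 to
        within machine precision, which the pruning recursion tolerates.
        """
        if t < 0 or not np.isfinite(t):
            raise ValueError(f"branch length must be finite and >= 0, got {t}")
        E = np.exp(np.multiply.outer(np.asarray(rates, float) * t, self._lam))
        P = (self._left[None, :, :] * E[:, None, :]) @ self._right
        np.maximum(P, 0.0, out=P)
        return P

    def __repr__(self):  # pragma: no cover
        return (
            f"<SubstitutionModel {self.name} alpha={self.alpha:.3g} "
            f"k={self.n_categories}>"
        )


def poisson_model(
    frequencies: np.ndarray | None = None,
    alpha: float = 1.0,
    n_categories: int = 4,
    name: str = "Poisson",
) -> SubstitutionModel:
    """Equal-exchangeability model; uniform frequencies unless given."""
    S = np.ones((N_STATES, N_STATES))
    np.fill_diagonal(S, 0.0)
    if frequencies is None:
        frequencies = np.full(N_STATES, 1.0 / N_STATES)
    return SubstitutionModel(name, S, np.asarray(frequencies, float), alpha,
                             n_categories)


def read_paml_matrix(
    path, name: str | None = None, alpha: float = 1.0, n_categories: int = 4
) -> SubstitutionModel:
    """Load a PAML-format amino-acid model file.

    Format: 19 rows of lower-triangle exchangeabilities (residue order
    ``ARNDCQEGHILKMFPSTWYV``) followed by a line (or lines) of 20 equilibrium
    frequencies.  Blank lines and ``#`` comments are ignored.
    """
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if line:
                values.extend(float(x) for x in line.split())
    n_tri = N_STATES * (N_STATES - 1) // 2
    if len(values) < n_tri + N_STATES:
        raise ValueError(
            f"PAML matrix file needs {n_tri} exchangeabilities + 20 frequencies, "
            f"found {len(values)} numbers"
        )
    S = np.zeros((N_STATES, N_STATES))
    k = 0
    for i in range(1, N_STATES):
        for j in range(i):
            S[i, j] = S[j, i] = values[k]
            k += 1
    pi = np.asarray(values[n_tri : n_tri + N_STATES], float)
    pi = pi / pi.sum()
    if name is None:
        import os

        name = os.path.splitext(os.path.basename(str(path)))[0]
    return SubstitutionModel(name, S, pi, alpha, n_categories)


def write_paml_matrix(model: SubstitutionModel, path) -> None:
    """Write exchangeabilities + frequencies in PAML format."""
    with open(path, "w") as fh:
        fh.write(f"# {model.name} (residue order {AA_LETTERS})\n")
        S = model.exchangeabilities
        for i in range(1, N_STATES):
            fh.write(" ".join(f"{S[i, j]:.6g}" for j in range(i)) + "\n")
        fh.write("\n")
        fh.write(" ".join(f"{f:.6g}" for f in model.frequencies) + "\n")
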