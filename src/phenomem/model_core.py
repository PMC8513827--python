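"""Core compartment model: parameter types, rate matrix, spectral analysis.

The model describes an isogenic microbial population whose cells occupy one
of ``n_on + 1`` compartments: a single 'off' (resting) compartment at index
0 and ``n_on`` 'on' substates at indices 1..n.  An 'off' cell switches at
rate ``mu`` and jumps to the freshest 'on' compartment ``n`` (full
potential).  'On' cells lose potential by leaching ``i -> i-1`` at a
constant rate ``epsilon``; compartment 1 leaches back to 'off'.  Each
compartment carries its own per-capita birth and death rates ``b_i`` and
``d_i``.  The number of 'on' compartments acts as a cellular memory: with
``n_on = 1`` the time spent 'on' is exponential (memory-less), while for
``n_on > 1`` it is gamma distributed with shape ``n_on`` and rate
``epsilon``.

The deterministic counterpart of the individual-cell reactions is the
linear system ``x' = A x`` whose rate matrix ``A`` is assembled by
:func:`build_rate_matrix`.  Because ``A`` is Metzler (non-negative
off-diagonal), it has a real dominant eigenvalue with a non-negative
eigenvector; the eigenvalue is the asymptotic per-capita growth rate and
the sum-normalised eigenvector is the equilibrium compartment
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class InvalidParameterError(ValueError):
    """Raised when a parameter set violates the model's invariants."""


@dataclass(frozen=True)
class ModelParams:
    """Full parameterisation of one lineage.

    Parameters
    ----------
    n_on : int
        Number of 'on' compartments (>= 1); total compartments ``n_on + 1``.
    mu : float
        'off' -> 'on' switch rate (per unit time, >= 0).
    epsilon : float
        Leaching rate between successive 'on' compartments and from
        compartment 1 back to 'off' (per unit time, > 0).
    birth, death : array-like or scalar
        Per-compartment birth/death rates ``b_i``, ``d_i`` for
        ``i = 0..n_on`` (index 0 = 'off').  A scalar is broadcast to all
        compartments.
    """

    n_on: int
    mu: float
    epsilon: float
    birth: np.ndarray
    death: np.ndarray

    def __post_init__(self) -> None:
        if int(self.n_on) != self.n_on or self.n_on < 1:
            raise InvalidParameterError(f"n_on must be a positive integer, got {self.n_on!r}")
        object.__setattr__(self, "n_on", int(self.n_on))
        if not self.mu >= 0:
            raise InvalidParameterError(f"mu must be >= 0, got {self.mu!r}")
        if not self.epsilon > 0:
            raise InvalidParameterError(f"epsilon must be > 0, got {self.epsilon!r}")
        m = self.n_on + 1
        for name in ("birth", "death"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.ndim == 0:
                v = np.full(m, float(v))
            if v.shape != (m,):
                raise InvalidParameterError(
                    f"{name} must be a scalar or a vector of length n_on + 1 = {m}, "
                    f"got shape {v.shape}"
                )
            if np.any(v < 0) or not np.all(np.isfinite(v)):
                raise InvalidParameterError(f"{name} entries must be finite and >= 0")
            v.flags.writeable = False
            object.__setattr__(self, name, v)

    @property
    def n_compartments(self) -> int:
        return self.n_on + 1

    @property
    def is_symmetric(self) -> bool:
        """True when all compartments share one birth and one death rate."""
        return bool(
            np.all(self.birth == self.birth[0]) and np.all(self.death == self.death[0])
        )

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)

    def with_n_on(self, n_on: int) -> "ModelParams":
        """Rebuild for a different memory length, keeping the 'off' rates at
        index 0 and broadcasting the (assumed uniform) 'on' rates."""
        on_b = self.birth[1] if self.n_on >= 1 else self.birth[0]
        on_d = self.death[1] if self.n_on >= 1 else self.death[0]
        birth = np.concatenate([[self.birth[0]], np.full(n_on, on_b)])
        death = np.concatenate([[self.death[0]], np.full(n_on, on_d)])
        return ModelParams(n_on=n_on, mu=self.mu, epsilon=self.epsilon,
                           birth=birth, death=death)

    # -- flat-dict (config file) serialisation ---------------------------
    def to_dict(self) -> dict:
        def compact(v: np.ndarray):
            return float(v[0]) if np.all(v == v[0]) else [float(x) for x in v]

        return {
            "n_on": self.n_on,
            "mu": float(self.mu),
            "epsilon": float(self.epsilon),
            "birth": compact(self.birth),
            "death": compact(self.death),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        required = {"n_on", "mu", "epsilon", "birth", "death"}
        missing = required - d.keys()
        if missing:
            raise InvalidParameterError(f"missing parameter keys: {sorted(missing)}")
        return cls(n_on=d["n_on"], mu=d["mu"], epsilon=d["epsilon"],
                   birth=d["birth"], death=d["death"])


@dataclass(frozen=True)
class CompartmentState:
    """Abundance vector over compartments 0..n at one time point."""

    time: float
    abundances: np.ndarray

    def __post_init__(self) -> None:
        if self.time < 0:
            raise InvalidParameterError(f"time must be >= 0, got {self.time}")
        x = np.asarray(self.abundances, dtype=float)
        if x.ndim != 1 or x.size < 2:
            raise InvalidParameterError("abundances must be a vector of length >= 2")
        if np.any(x < 0):
            raise InvalidParameterError("abundances must be non-negative")
        x = x.copy()
        x.flags.writeable = False
        object.__setattr__(self, "abundances", x)

    @property
    def total_population(self) -> float:
        return float(self.abundances.sum())

    @property
    def fraction_on(self) -> float:
        """(N - x_0)/N; undefined (raises) for an empty population."""
        n = self.total_population
        if n <= 0:
            raise ValueError("fraction_on undefined for an empty population")
        return float((n - self.abundances[0]) / n)

    @classmethod
    def all_off(cls, n_on: int, n_cells: float, time: float = 0.0) -> "CompartmentState":
        """Start with the whole population in the 'off' compartment."""
        x = np.zeros(n_on + 1)
        x[0] = n_cells
        return cls(time=time, abundances=x)


@dataclass(frozen=True)
class SpectralSummary:
    """Eigen-structure of the rate matrix.

    ``growth_rate`` is the dominant (Perron) eigenvalue, i.e. the asymptotic
    per-capita growth rate; ``equilibrium_distribution`` is the matching
    right eigenvector normalised to sum 1 (the stable compartment
    distribution); ``spectral_gap`` = Re(dominant) - max Re(subdominant)
    controls how fast transients decay.
    """

    growth_rate: float
    equilibrium_distribution: np.ndarray
    subdominant_eigenvalues: tuple
    spectral_gap: float
    defective_warning: bool = field(default=False)

    @property
    def has_complex_subdominant(self) -> bool:
        return any(abs(ev.imag) > 1e-12 for ev in self.subdominant_eigenvalues)

    @property
    def equilibrium_on_fraction(self) -> float:
        return float(1.0 - self.equilibrium_distribution[0])


def build_rate_matrix(params: ModelParams) -> np.ndarray:
    """Assemble the (n_on+1) x (n_on+1) rate matrix A with x' = A x.

    Row/column convention: ``A[row, col]`` multiplies ``x_col`` in the
    equation for ``x_row``.  Off compartment: loses switchers at rate mu,
    gains leachers from compartment 1.  Freshest compartment n: gains
    switchers, loses leachers.  Interior 0 < i < n: gains from i+1, loses
    to i-1.  Columns therefore sum to ``b_j - d_j``: switching and leaching
    only move cells, births and deaths alone change the total.
    """
    n = params.n_on
    g = params.birth - params.death  # net per-compartment growth
    A = np.zeros((n + 1, n + 1))
    A[0, 0] = g[0] - params.mu
    A[0, 1] = params.epsilon
    A[n, n] = g[n] - params.epsilon
    A[n, 0] += params.mu
    for i in range(1, n):
        A[i, i] = g[i] - params.epsilon
        A[i, i + 1] = params.epsilon
    return A


_TIE_TOL = 1e-12


def spectral_summary(params: ModelParams) -> SpectralSummary:
    """Full eigen-decomposition of the rate matrix.

    The dominant eigenvalue is selected by maximal real part; the matrix is
    Metzler, so this eigenvalue is real and carries a sign-constant
    eigenvector (on numerical ties within 1e-12 the candidate whose
    eigenvector is sign-constant is preferred).  The eigenvector is flipped
    so its largest-magnitude entry is positive, entries in [-1e-12, 0) are
    clipped to 0, and the result renormalised to sum 1.
    """
    A = build_rate_matrix(params)
    eigvals, eigvecs = np.linalg.eig(A)

    max_re = eigvals.real.max()
    candidates = np.flatnonzero(eigvals.real >= max_re - _TIE_TOL)
    dom = candidates[0]
    if len(candidates) > 1:
        for k in candidates:
            v = eigvecs[:, k].real
            if np.all(v >= -_TIE_TOL) or np.all(v <= _TIE_TOL):
                dom = k
                break

    # defective if a *distinct* eigenvalue nearly coincides with the dominant
    close = np.abs(eigvals - eigvals[dom]) < 1e-9
    defective = int(close.sum()) > 1

    v = eigvecs[:, dom].real.copy()
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    v[(v >= -_TIE_TOL) & (v < 0)] = 0.0
    if np.any(v < 0):  # pragma: no cover - Metzler structure forbids this
        defective = True
        v = np.clip(v, 0.0, None)
    v /= v.sum()
    v.flags.writeable = False

    rest = np.delete(eigvals, dom)
    order = np.argsort(-rest.real, kind="stable")
    sub = tuple(complex(ev) for ev in rest[order])
    gap = float(eigvals[dom].real - rest.real.max()) if len(rest) else 0.0

    return SpectralSummary(
        growth_rate=float(eigvals[dom].real),
        equilibrium_distribution=v,
        subdominant_eigenvalues=sub,
        spectral_gap=max(gap, 0.0),
        defective_warning=defective,
    )


def equilibrium_on_fraction(params: ModelParams) -> float:
    """Closed-form equilibrium 'on' fraction n*mu/(epsilon + n*mu).

    Valid only under fully symmetric growth (b_i all equal, d_i all equal),
    where the stable distribution is flat across the 'on' compartments.
    """
    if not params.is_symmetric:
        raise InvalidParameterError(
            "closed-form equilibrium requires symmetric growth rates; "
            "use spectral_summary() for asymmetric parameters"
        )
    nmu = params.n_on * params.mu
    return float(nmu / (params.epsilon + nmu))


def calibrate_epsilon(n_on: int, mu: float, target_fraction: float) -> float:
    """Leaching rate giving equilibrium 'on' fraction ``q`` for given n, mu.

    Inverts q = n*mu/(eps + n*mu):  eps = n*mu*(1 - q)/q.
    """
    if not 0 < target_fraction < 1:
        raise InvalidParameterError("target_fraction must lie strictly in (0, 1)")
    return n_on * mu * (1.0 - target_fraction) / target_fraction


def memoryless_equivalent_epsilon(params: ModelParams) -> float:
    """Leaching rate eps' for an n_on = 1 lineage with the same equilibrium
    'on' fraction: mu/(eps' + mu) = n*mu/(eps + n*mu)  =>  eps' = eps/n.

    The calibrated memory-less lineage also matches the mean 'on' residence
    time n/eps of the memory lineage (gamma(n, eps) mean equals
    exponential(eps/n) mean).
    """
    if not params.is_symmetric:
        raise InvalidParameterError(
            "memoryless calibration is defined for symmetric growth rates"
        )
    return params.epsilon / params.n_on


def memoryless_counterpart(params: ModelParams) -> ModelParams:
    """The n_on = 1 lineage calibrated to the same equilibrium 'on' fraction."""
    return params.with_n_on(1).replace(epsilon=memoryless_equivalent_epsilon(params))


# -- tabular export -----------------------------------------------------

def spectral_summary_to_tsv(summary: SpectralSummary, path) -> None:
    """Write the eigenvalue table and the equilibrium distribution.

    Two '#'-headed sections in one tab-separated file: one row per
    eigenvalue (real, imag, is_dominant) then one row per compartment.
    """
    lines = ["# eigenvalues", "real\timag\tis_dominant"]
    lines.append(f"{summary.growth_rate!r}\t0.0\t1")
    for ev in summary.subdominant_eigenvalues:
        lines.append(f"{ev.real!r}\t{ev.imag!r}\t0")
    lines += ["", "# equilibrium_distribution", "compartment\tfraction"]
    for i, f in enumerate(summary.equilibrium_distribution):
        lines.append(f"{i}\t{f!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
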