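"""Stochastic simulation engines: exact SSA and adaptive tau-leaping.

Both engines operate on the flat-array form of a
:class:`~jakstat.model.ReactionNetwork` and record states on a fixed time
grid (copy numbers are piecewise constant between reaction events, so the
recorded state at a grid point is the state left by the last event before
it).  Trajectories of an ensemble use independent RNG substreams spawned
from a single master seed, so every ensemble is exactly reproducible from
its metadata.

The tau-leaping engine follows the standard adaptive partitioning scheme:
reactions that consume a scarce reactant (below ``N_CRITICAL`` copies) are
"critical" and fire one at a time with exact exponential waiting times; the
remaining reactions advance by Poisson leaps whose step keeps the expected
relative propensity change below ``eps``.  Leaps that would drive a copy
number negative are rejected and redrawn with a halved step, and when the
permissible leap would cover only a handful of events the engine falls back
to exact SSA steps.  Promoter microstates therefore always evolve exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .model import ParameterSet, ReactionNetwork, SpeciesRole

__all__ = [
    "Trajectory",
    "Ensemble",
    "ssa_exact",
    "tau_leap_adaptive",
    "run_ensemble",
    "draw_initial_state",
]

DEFAULT_EPS = 0.03
N_CRITICAL = 10
#: fall back to exact SSA when a leap would cover fewer expected events
FALLBACK_EVENTS = 10.0
FALLBACK_STEPS = 100
MAX_SPECIES_PER_RXN = 4


# --------------------------------------------------------------------------
# kernels
# --------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _poisson(lam):
    # inversion by uniform products for small means, library sampler above
    if lam <= 0.0:
        return 0
    if lam < 10.0:
        L = np.exp(-lam)
        k = 0
        p = np.random.random()
        while p > L:
            p *= np.random.random()
            k += 1
        return k
    return np.random.poisson(lam)


@njit(cache=True, fastmath=True)
def _props(x, rates, r1, r2, a):
    total = 0.0
    for j in range(rates.shape[0]):
        aj = rates[j]
        i1 = r1[j]
        if i1 >= 0:
            aj *= x[i1]
            i2 = r2[j]
            if i2 >= 0:
                aj *= x[i2]
        a[j] = aj
        total += aj
    return total


@njit(cache=True)
def _ssa_steps(x, t, g, max_steps, rates, r1, r2, s_n, s_idx, s_val, t_grid, a, out):
    """Advance by at most max_steps exact SSA events; returns (t, g, frozen)."""
    n_grid = t_grid.shape[0]
    steps = 0
    while steps < max_steps and g < n_grid:
        a0 = _props(x, rates, r1, r2, a)
        if a0 <= 0.0:
            return t, g, True
        t_next = t + np.random.exponential(1.0 / a0)
        while g < n_grid and t_grid[g] < t_next:
            for i in range(x.shape[0]):
                out[g, i] = x[i]
            g += 1
        if g >= n_grid:
            return t_next, g, False
        u = np.random.random() * a0
        acc = 0.0
        jr = rates.shape[0] - 1
        for j in range(rates.shape[0]):
            acc += a[j]
            if u < acc:
                jr = j
                break
        for m in range(s_n[jr]):
            x[s_idx[jr, m]] += s_val[jr, m]
        t = t_next
        steps += 1
    return t, g, False


@njit(cache=True)
def _ssa_kernel(x0, rates, r1, r2, s_n, s_idx, s_val, t_grid, seed, out):
    np.random.seed(seed)
    n_grid = t_grid.shape[0]
    x = x0.copy()
    a = np.empty(rates.shape[0])
    for i in range(x.shape[0]):
        out[0, i] = x[i]
    t = t_grid[0]
    g = 1
    while g < n_grid:
        t, g, frozen = _ssa_steps(
            x, t, g, 1 << 30, rates, r1, r2, s_n, s_idx, s_val, t_grid, a, out
        )
        if frozen:
            while g < n_grid:
                for i in range(x.shape[0]):
                    out[g, i] = x[i]
                g += 1
    return 0


@njit(cache=True)
def _tau_kernel(
    x0,
    rates,
    r1,
    r2,
    s_n,
    s_idx,
    s_val,
    c_n,
    c_idx,
    t_grid,
    eps,
    n_crit,
    seed,
    out,
):
    np.random.seed(seed)
    n_grid = t_grid.shape[0]
    n_r = rates.shape[0]
    n_s = x0.shape[0]
    x = x0.copy()
    a = np.empty(n_r)
    mu = np.empty(n_s)
    sig2 = np.empty(n_s)
    dx = np.zeros(n_s, dtype=np.int64)
    is_crit = np.empty(n_r, dtype=np.uint8)
    constrain = np.empty(n_s, dtype=np.uint8)
    for i in range(n_s):
        out[0, i] = x[i]
    t = t_grid[0]
    g = 1
    while g < n_grid:
        a0 = _props(x, rates, r1, r2, a)
        if a0 <= 0.0:
            while g < n_grid:
                for i in range(n_s):
                    out[g, i] = x[i]
                g += 1
            break

        # partition and accumulate Cao's step-size statistics; only species
        # that are reactants of at least one leapable reaction constrain the
        # step (scarce species whose consumption is critical evolve exactly)
        for i in range(n_s):
            mu[i] = 0.0
            sig2[i] = 0.0
            constrain[i] = 0
        a0_crit = 0.0
        for j in range(n_r):
            if a[j] <= 0.0:
                is_crit[j] = 0
                continue
            crit = 0
            for m in range(c_n[j]):
                if x[c_idx[j, m]] < n_crit:
                    crit = 1
                    break
            is_crit[j] = crit
            if crit == 1:
                a0_crit += a[j]
            else:
                for m in range(c_n[j]):
                    constrain[c_idx[j, m]] = 1
                for m in range(s_n[j]):
                    i = s_idx[j, m]
                    v = s_val[j, m]
                    mu[i] += v * a[j]
                    sig2[i] += v * v * a[j]
                    # a scarce species fed by a leapable channel must also
                    # bound the step, or it would receive multi-molecule
                    # bursts that its (critical) consumption cannot resolve
                    if v > 0 and x[i] < n_crit:
                        constrain[i] = 1

        tau1 = 1.0e30
        for i in range(n_s):
            si = sig2[i]
            if si == 0.0 or constrain[i] == 0:
                continue
            bound = eps * x[i] * 0.5
            if bound < 1.0:
                bound = 1.0
            mi = mu[i]
            if mi < 0.0:
                mi = -mi
            if mi > 0.0:
                c = bound / mi
                if c < tau1:
                    tau1 = c
            c = bound * bound / si
            if c < tau1:
                tau1 = c

        if tau1 * a0 < FALLBACK_EVENTS:
            t, g, frozen = _ssa_steps(
                x, t, g, FALLBACK_STEPS, rates, r1, r2, s_n, s_idx, s_val, t_grid, a, out
            )
            if frozen:
                while g < n_grid:
                    for i in range(n_s):
                        out[g, i] = x[i]
                    g += 1
            continue

        if a0_crit > 0.0:
            tau2 = np.random.exponential(1.0 / a0_crit)
        else:
            tau2 = 1.0e30

        # steps are not aligned with the recording grid: grid points falling
        # inside a step record the pre-step state (the state is piecewise
        # constant and the leap condition bounds the per-step change, so the
        # staleness stays within the eps tolerance)
        max_tau = t_grid[n_grid - 1] - t + 1.0
        attempts = 0
        while True:
            tau = tau1
            fire_crit = False
            if tau2 < tau:
                tau = tau2
                fire_crit = a0_crit > 0.0
            if tau > max_tau:
                tau = max_tau
                fire_crit = False
            if tau < 1.0e-9:
                attempts += 1
                if attempts > 200:
                    return 1

            for i in range(n_s):
                dx[i] = 0
            a0_leap = a0 - a0_crit
            lam_tot = a0_leap * tau
            if lam_tot < 2.0:
                # superposition: draw the total event count once, then
                # attribute events to channels proportionally to propensity
                # (exactly equivalent to independent per-channel Poissons)
                n_ev = _poisson(lam_tot)
                for _ in range(n_ev):
                    u = np.random.random() * a0_leap
                    acc = 0.0
                    for j in range(n_r):
                        if a[j] <= 0.0 or is_crit[j] == 1:
                            continue
                        acc += a[j]
                        if u < acc:
                            for m in range(s_n[j]):
                                dx[s_idx[j, m]] += s_val[j, m]
                            break
            else:
                for j in range(n_r):
                    if a[j] <= 0.0 or is_crit[j] == 1:
                        continue
                    k = _poisson(a[j] * tau)
                    if k > 0:
                        for m in range(s_n[j]):
                            dx[s_idx[j, m]] += k * s_val[j, m]
            if fire_crit:
                u = np.random.random() * a0_crit
                acc = 0.0
                jc = -1
                for j in range(n_r):
                    if is_crit[j] == 1:
                        acc += a[j]
                        if u < acc:
                            jc = j
                            break
                if jc >= 0:
                    for m in range(s_n[jc]):
                        dx[s_idx[jc, m]] += s_val[jc, m]

            ok = True
            for i in range(n_s):
                if x[i] + dx[i] < 0:
                    ok = False
                    break
            if ok:
                t_next = t + tau
                while g < n_grid and t_grid[g] <= t_next:
                    for i in range(n_s):
                        out[g, i] = x[i]
                    g += 1
                for i in range(n_s):
                    x[i] += dx[i]
                t = t_next
                break
            tau1 *= 0.5
            attempts += 1
            if attempts > 200:
                return 1
    return 0


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class Trajectory:
    """A single stochastic path recorded on a fixed time grid (minutes)."""

    time_grid: np.ndarray
    states: np.ndarray  # (n_times, n_species) int64
    rng_stream_id: int = 0


@dataclass
class Ensemble:
    """A set of trajectories sharing one time grid and species ordering."""

    time_grid: np.ndarray
    states: np.ndarray  # (n_reps, n_times, n_species) int64
    species_names: list[str]
    metadata: dict

    @property
    def n_reps(self) -> int:
        return self.states.shape[0]

    @property
    def trajectories(self) -> list[Trajectory]:
        return [
            Trajectory(self.time_grid, self.states[r], r)
            for r in range(self.n_reps)
        ]

    def _sp(self, species: str) -> int:
        return self.species_names.index(species)

    def _ti(self, time_min: float) -> int:
        i = int(np.argmin(np.abs(self.time_grid - time_min)))
        if abs(self.time_grid[i] - time_min) > 0.5 + 1e-9:
            raise ValueError(f"time {time_min} min not on recording grid")
        return i

    def marginal(self, species: str, time_min: float) -> np.ndarray:
        """Per-trajectory copy numbers of one species at one grid time."""
        return self.states[:, self._ti(time_min), self._sp(species)].astype(float)

    def species_matrix(self, species: str) -> np.ndarray:
        """(n_reps, n_times) copy-number matrix of one species."""
        return self.states[:, :, self._sp(species)].astype(float)

    def mean(self, species: str) -> np.ndarray:
        return self.species_matrix(species).mean(axis=0)

    # -- I/O -------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Long-format CSV (trajectory_id, time_min, species, copy_number)
        plus a JSON metadata sidecar."""
        path = Path(path)
        n_reps, n_t, n_s = self.states.shape
        df = pd.DataFrame(
            {
                "trajectory_id": np.repeat(np.arange(n_reps), n_t * n_s),
                "time_min": np.tile(np.repeat(self.time_grid, n_s), n_reps),
                "species": np.tile(self.species_names, n_reps * n_t),
                "copy_number": self.states.reshape(-1),
            }
        )
        df.to_csv(path, index=False)
        sidecar = dict(self.metadata)
        sidecar["format_version"] = 1
        sidecar["species_names"] = self.species_names
        Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Ensemble":
        path = Path(path)
        meta = json.loads(Path(str(path) + ".meta.json").read_text())
        if meta.get("format_version") != 1:
            raise ValueError(
                f"unsupported ensemble CSV format version {meta.get('format_version')!r}"
            )
        names = meta.pop("species_names")
        df = pd.read_csv(path)
        t_grid = np.sort(df["time_min"].unique())
        n_reps = df["trajectory_id"].nunique()
        order = {n: i for i, n in enumerate(names)}
        df = df.sort_values(["trajectory_id", "time_min"], kind="stable")
        df["_s"] = df["species"].map(order)
        df = df.sort_values(["trajectory_id", "time_min", "_s"], kind="stable")
        states = df["copy_number"].to_numpy(dtype=np.int64).reshape(
            n_reps, len(t_grid), len(names)
        )
        return cls(t_grid.astype(float), states, list(names), meta)

    def save_npz(self, path: str | Path) -> None:
        """Compact binary cache (runtime artifact)."""
        np.savez_compressed(
            path,
            time_grid=self.time_grid,
            states=self.states,
            species_names=np.array(self.species_names),
            metadata=json.dumps(self.metadata),
        )

    @classmethod
    def load_npz(cls, path: str | Path) -> "Ensemble":
        z = np.load(path, allow_pickle=False)
        return cls(
            z["time_grid"],
            z["states"],
            [str(s) for s in z["species_names"]],
            json.loads(str(z["metadata"])),
        )


# --------------------------------------------------------------------------
# initial-condition discretization
# --------------------------------------------------------------------------


def draw_initial_state(
    network: ReactionNetwork,
    rng: np.random.Generator,
    sampler=None,
) -> np.ndarray:
    """Integer initial state for one trajectory.

    Promoter microstates are drawn per gene from the fractional occupancies
    of the network's initial conditions (a single gene copy occupies exactly
    one of its three states); molecular species start at their initial
    values, optionally randomized by ``sampler`` (see
    :class:`jakstat.noise.InitialConditionSampler`).
    """
    x0 = network.initial_state()
    if sampler is not None:
        x0 = sampler.sample_molecular(x0, network, rng)
    x = np.rint(x0).astype(np.int64)
    for g, (i_free, i_a, i_b) in network.promoter_triples().items():
        probs = np.array([x0[i_free], x0[i_a], x0[i_b]], dtype=float)
        # fractional occupancies are probabilities; they sum to 1 per gene
        probs = np.clip(probs, 0.0, None)
        probs /= probs.sum()
        pick = rng.choice(3, p=probs)
        x[i_free], x[i_a], x[i_b] = 0, 0, 0
        x[[i_free, i_a, i_b][pick]] = 1
    if np.any(x < 0):
        raise ValueError("negative initial copy number")
    return x


# --------------------------------------------------------------------------
# public simulation API
# --------------------------------------------------------------------------


def _sparse_arrays(network: ReactionNetwork, params: ParameterSet | None):
    c = network.compiled(params)
    n_r = c.stoich.shape[0]
    s_n = np.zeros(n_r, dtype=np.int64)
    s_idx = np.zeros((n_r, MAX_SPECIES_PER_RXN), dtype=np.int64)
    s_val = np.zeros((n_r, MAX_SPECIES_PER_RXN), dtype=np.int64)
    c_n = np.zeros(n_r, dtype=np.int64)
    c_idx = np.zeros((n_r, 2), dtype=np.int64)
    for j in range(n_r):
        nz = np.nonzero(c.stoich[j])[0]
        if len(nz) > MAX_SPECIES_PER_RXN:
            raise ValueError("reaction touches too many species")
        s_n[j] = len(nz)
        s_idx[j, : len(nz)] = nz
        s_val[j, : len(nz)] = c.stoich[j, nz]
        cons = np.nonzero(c.consumed[j])[0]
        c_n[j] = len(cons)
        c_idx[j, : len(cons)] = cons
    return c, s_n, s_idx, s_val, c_n, c_idx


def _as_seed(rng) -> int:
    if isinstance(rng, np.random.Generator):
        return int(rng.integers(1, 2**31 - 1))
    return int(rng)


def ssa_exact(
    network: ReactionNetwork,
    params: ParameterSet | None,
    t_grid: np.ndarray,
    rng,
    x0: np.ndarray | None = None,
) -> Trajectory:
    """Exact Gillespie (direct method) trajectory recorded on ``t_grid``."""
    t_grid = _check_grid(t_grid)
    c, s_n, s_idx, s_val, c_n, c_idx = _sparse_arrays(network, params)
    if x0 is None:
        x0 = np.rint(network.initial_state()).astype(np.int64)
    out = np.empty((len(t_grid), network.n_species), dtype=np.int64)
    seed = _as_seed(rng)
    _ssa_kernel(
        np.asarray(x0, dtype=np.int64),
        c.rates,
        c.reactant1,
        c.reactant2,
        s_n,
        s_idx,
        s_val,
        t_grid,
        seed,
        out,
    )
    return Trajectory(t_grid, out, seed)


def tau_leap_adaptive(
    network: ReactionNetwork,
    params: ParameterSet | None,
    t_grid: np.ndarray,
    eps: float = DEFAULT_EPS,
    rng=0,
    x0: np.ndarray | None = None,
) -> Trajectory:
    """Adaptive explicit tau-leap trajectory (exact handling of scarce
    species) recorded on ``t_grid``."""
    if not 0.0 < eps <= 0.1:
        raise ValueError("eps must lie in (0, 0.1]")
    t_grid = _check_grid(t_grid)
    c, s_n, s_idx, s_val, c_n, c_idx = _sparse_arrays(network, params)
    if x0 is None:
        x0 = np.rint(network.initial_state()).astype(np.int64)
    out = np.empty((len(t_grid), network.n_species), dtype=np.int64)
    seed = _as_seed(rng)
    status = _tau_kernel(
        np.asarray(x0, dtype=np.int64),
        c.rates,
        c.reactant1,
        c.reactant2,
        s_n,
        s_idx,
        s_val,
        c_n,
        c_idx,
        t_grid,
        eps,
        N_CRITICAL,
        seed,
        out,
    )
    if status != 0:
        raise RuntimeError("tau-leap step size underflow (tau < 1e-9 min)")
    return Trajectory(t_grid, out, seed)


def _check_grid(t_grid) -> np.ndarray:
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    return t_grid


def run_ensemble(
    network: ReactionNetwork,
    params: ParameterSet | None = None,
    n_reps: int = 1000,
    t_grid: np.ndarray | None = None,
    sampler=None,
    master_seed: int = 0,
    engine: str = "tau",
    eps: float = DEFAULT_EPS,
    initial_states: np.ndarray | None = None,
) -> Ensemble:
    """Simulate ``n_reps`` independent single-cell trajectories.

    Each trajectory gets its own RNG substream derived from ``master_seed``;
    its initial state is drawn by :func:`draw_initial_state` (promoter
    microstates resampled from their occupancy probabilities, molecular
    species randomized by ``sampler`` if given).  Alternatively,
    ``initial_states`` supplies one explicit integer state per trajectory
    (e.g. the endpoints of a basal burn-in ensemble).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if initial_states is not None:
        initial_states = np.asarray(initial_states, dtype=np.int64)
        if initial_states.shape != (n_reps, network.n_species):
            raise ValueError(
                f"initial_states must have shape ({n_reps}, {network.n_species})"
            )
    if engine not in ("tau", "exact"):
        raise ValueError(f"unknown engine {engine!r}")
    if t_grid is None:
        t_grid = np.arange(0.0, 1921.0, 1.0)
    t_grid = _check_grid(t_grid)
    if not 0.0 < eps <= 0.1:
        raise ValueError("eps must lie in (0, 0.1]")
    c, s_n, s_idx, s_val, c_n, c_idx = _sparse_arrays(network, params)
    states = np.empty((n_reps, len(t_grid), network.n_species), dtype=np.int64)
    children = np.random.SeedSequence(master_seed).spawn(n_reps)
    for r in range(n_reps):
        rng = np.random.Generator(np.random.Philox(children[r]))
        kernel_seed = int(rng.integers(1, 2**31 - 1))
        if initial_states is not None:
            x0 = initial_states[r]
        else:
            x0 = draw_initial_state(network, rng, sampler)
        if engine == "tau":
            status = _tau_kernel(
                x0, c.rates, c.reactant1, c.reactant2,
                s_n, s_idx, s_val, c_n, c_idx,
                t_grid, eps, N_CRITICAL, kernel_seed, states[r],
            )
            if status != 0:
                raise RuntimeError(
                    f"tau-leap step size underflow in trajectory {r}"
                )
        else:
            _ssa_kernel(
                x0, c.rates, c.reactant1, c.reactant2,
                s_n, s_idx, s_val, t_grid, kernel_seed, states[r],
            )
    metadata = {
        "master_seed": int(master_seed),
        "engine": engine,
        "eps": float(eps),
        "n_reps": int(n_reps),
        "sigma": getattr(sampler, "sigma", 0.0),
        "ifn_initial": float(network.initial_state()[network.species_index("IFN")])
        if "IFN" in network.species_names
        else None,
    }
    return Ensemble(t_grid, states, network.species_names, metadata)
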