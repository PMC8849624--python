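"""Concentration-driven receptor state models.

Glutamate receptor gating is computed deterministically from the simulated
concentration waveform: the state-probability vector follows the master
equation ``dP/dt = Q([glu](t)) P`` where glutamate-dependent transitions are
scaled by the instantaneous concentration.  This is accurate for receptors
present at low copy number, where stochastic single-channel simulation would
only add sampling noise.

The exact published rate constants for hippocampal AMPA/NMDA receptors are
not part of this package; schemes are loaded from a JSON rate-matrix format,
and the bundled defaults are synthetic generic multi-state schemes with
literature-plausible magnitudes (two sequential glutamate binding steps, an
opening/closing equilibrium and a desensitised state).  Absolute open
probabilities therefore carry no quantitative claim; relative trends across
transporter densities and release sites do.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import interp1d

__all__ = [
    "ReceptorScheme",
    "receptor_open_probability",
    "generic_ampa_scheme",
    "generic_nmda_scheme",
]


@dataclass(frozen=True)
class ReceptorScheme:
    """Markov receptor model with glutamate-dependent entries.

    ``rates`` maps (from_state, to_state) -> rate; glutamate-dependent
    entries (units M^-1 s^-1) are multiplied by [glu](t), others are s^-1.
    ``q10_factor`` rescales every rate (temperature adjustment, Q10 = 3 per
    10 C when applicable); the bundled transporter rates are already at
    35 C, so the default factor is 1.
    """

    states: tuple[str, ...]
    open_states: tuple[str, ...]
    rates: dict = field(default_factory=dict)
    glu_dependent: frozenset = frozenset()
    q10_factor: float = 1.0

    def __post_init__(self) -> None:
        for s in self.open_states:
            if s not in self.states:
                raise ValueError(f"open state {s!r} not among states")
        for (a, b) in self.rates:
            if a not in self.states or b not in self.states:
                raise ValueError(f"transition {a}->{b} uses unknown states")

    def generators(self) -> tuple[np.ndarray, np.ndarray]:
        """(Q0, Q1): ``Q(c) = Q0 + c Q1``, columns sum to zero."""
        n = len(self.states)
        idx = {s: i for i, s in enumerate(self.states)}
        q0 = np.zeros((n, n))
        q1 = np.zeros((n, n))
        for (a, b), k in self.rates.items():
            m = q1 if (a, b) in self.glu_dependent else q0
            k = k * self.q10_factor
            m[idx[b], idx[a]] += k
            m[idx[a], idx[a]] -= k
        return q0, q1

    @property
    def open_index(self) -> np.ndarray:
        return np.array([self.states.index(s) for s in self.open_states])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "states": list(self.states),
            "open": list(self.open_states),
            "q10_factor": self.q10_factor,
            "rates": [{"from": a, "to": b, "rate": k,
                       "glu_dependent": (a, b) in self.glu_dependent}
                      for (a, b), k in self.rates.items()],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReceptorScheme":
        d = json.loads(Path(path).read_text())
        rates = {(r["from"], r["to"]): r["rate"] for r in d["rates"]}
        dep = frozenset((r["from"], r["to"]) for r in d["rates"] if r["glu_dependent"])
        return cls(states=tuple(d["states"]), open_states=tuple(d["open"]),
                   rates=rates, glu_dependent=dep,
                   q10_factor=d.get("q10_factor", 1.0))

    def stationary_distribution(self, glu_M: float) -> np.ndarray:
        """Null-space stationary distribution of Q(c); oracle for long runs."""
        q0, q1 = self.generators()
        q = q0 + glu_M * q1
        w, v = np.linalg.eig(q)
        i = int(np.argmin(np.abs(w)))
        p = np.real(v[:, i])
        p = np.abs(p)
        return p / p.sum()


def generic_ampa_scheme(q10_factor: float = 1.0) -> ReceptorScheme:
    """Synthetic generic fast ionotropic (AMPA-like) scheme.

    Two sequential binding steps, fast opening/closing, one desensitised
    state.  Magnitudes are representative of fast hippocampal receptors, not
    a published parameter set.
    """
    rates = {
        ("C0", "C1"): 9.2e6,   # M^-1 s^-1 (2 sites available)
        ("C1", "C0"): 4.26e3,
        ("C1", "C2"): 4.6e6,   # M^-1 s^-1
        ("C2", "C1"): 8.52e3,
        ("C2", "O"): 4.24e3,
        ("O", "C2"): 900.0,
        ("C2", "D"): 1.8e3,
        ("D", "C2"): 64.0,
    }
    dep = frozenset({("C0", "C1"), ("C1", "C2")})
    return ReceptorScheme(states=("C0", "C1", "C2", "O", "D"),
                          open_states=("O",), rates=rates, glu_dependent=dep,
                          q10_factor=q10_factor)


def generic_nmda_scheme(q10_factor: float = 1.0) -> ReceptorScheme:
    """Synthetic generic slow ionotropic (NMDA-like) scheme.

    Higher affinity, slow gating, shallow desensitisation; magnitudes are
    representative only.
    """
    rates = {
        ("C0", "C1"): 1.0e7,
        ("C1", "C0"): 60.0,
        ("C1", "C2"): 5.0e6,
        ("C2", "C1"): 120.0,
        ("C2", "O"): 93.0,
        ("O", "C2"): 47.0,
        ("C2", "D"): 8.4,
        ("D", "C2"): 1.8,
    }
    dep = frozenset({("C0", "C1"), ("C1", "C2")})
    return ReceptorScheme(states=("C0", "C1", "C2", "O", "D"),
                          open_states=("O",), rates=rates, glu_dependent=dep,
                          q10_factor=q10_factor)


def receptor_open_probability(times_us: np.ndarray, glu_uM: np.ndarray,
                              scheme: ReceptorScheme,
                              p0: np.ndarray | None = None,
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Open probability Po(t) driven by a concentration waveform.

    Integrates ``dP/dt = Q([glu](t)) P`` from the resting state (all
    probability in the first state unless ``p0`` is given) with a stiff
    solver; the probability simplex is preserved to 1e-8 and renormalised in
    the output.  Returns (Po(t), P(t) matrix states x time).
    """
    times_us = np.asarray(times_us, dtype=float)
    glu_uM = np.asarray(glu_uM, dtype=float)
    if np.any(glu_uM < 0):
        raise ValueError("concentration waveform must be non-negative")
    if times_us.shape != glu_uM.shape:
        raise ValueError("times and waveform must have matching shapes")
    q0, q1 = scheme.generators()
    n = len(scheme.states)
    if p0 is None:
        p0 = np.zeros(n)
        p0[0] = 1.0
    conc = interp1d(times_us * 1e-6, glu_uM * 1e-6, kind="linear",
                    bounds_error=False,
                    fill_value=(glu_uM[0] * 1e-6, glu_uM[-1] * 1e-6))

    def rhs(t, p):
        return (q0 + float(conc(t)) * q1) @ p

    t_s = times_us * 1e-6
    sol = solve_ivp(rhs, (t_s[0], t_s[-1]), p0, t_eval=t_s, method="LSODA",
                    rtol=1e-8, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"receptor master-equation integration failed: {sol.message}")
    p = sol.y
    drift = np.abs(p.sum(axis=0) - 1.0)
    if drift.max() > 1e-6:
        raise RuntimeError(f"probability not conserved (max drift {drift.max():.2e})")
    p = p / p.sum(axis=0, keepdims=True)
    po = p[scheme.open_index].sum(axis=0)
    return po, p
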