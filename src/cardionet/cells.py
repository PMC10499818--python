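"""Pluggable per-node membrane kinetics.

The tissue solvers only require the small interface of :class:`CellModel`
(resting state, ionic current, forward-Euler step over arrays of cells),
so any cell model — from the bundled two-variable model up to a detailed
ionic model — can be dropped in.

The bundled default is the Mitchell–Schaeffer two-variable excitable model
mapped onto a physiological voltage range (rest −85 mV, peak ≈ +20 mV,
APD ≈ 200 ms), standing in for a hybrid minimal ventricular model.  It
reproduces the qualitative features tissue simulations need — threshold,
a fast upstroke, a plateau, repolarisation and refractoriness — while
remaining smooth enough for explicit integration at the time steps used
in tissue simulation (0.0001–0.05 ms).

All currents are per-capacitance (mV/ms): the membrane capacitance is
absorbed into the conductances, so ``dV/dt = I_coupling - I_ion``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CellModel", "MitchellSchaeffer", "PassiveMembrane"]


class CellModel:
    """Interface the tissue solvers integrate against."""

    V_rest: float
    V_peak: float
    gate_names: tuple[str, ...] = ()

    def initial_state(self, n: int):
        """Resting state: ``(V, gates)`` with arrays of length ``n``."""
        raise NotImplementedError

    def ionic_current(self, V, gates, stimulus=0.0):
        """Total I_ion (mV/ms) including any applied stimulus current.

        Sign convention: ``dV/dt = sum(I_gap) - I_ion``, so a stimulus
        ``I_stim`` (depolarising, positive) enters as ``-I_stim``.
        """
        raise NotImplementedError

    def step(self, V, gates, I_total, dt):
        """Advance V and gates in place by one forward-Euler step.

        ``I_total`` is the per-node external current (coupling + stimulus,
        mV/ms).
        """
        raise NotImplementedError


@dataclass
class MitchellSchaeffer(CellModel):
    """Two-variable excitable model on a physical voltage scale.

    The dimensionless excitation variable ``u = (V - V_rest)/amplitude``
    obeys

        du/dt = h * u^2 * (1 - u) / tau_in  -  u / tau_out

    and the recovery gate ``h`` opens with ``tau_open`` below the gate
    threshold ``u_gate`` and closes with ``tau_close`` above it.  Defaults
    are the model's standard parameter set except ``tau_close``, shortened
    to put the action-potential duration in the ventricular range
    (APD90 ≈ 230 ms); ``tau_in`` sets the upstroke speed and hence, with
    the coupling, the conduction velocity.
    """

    tau_in: float = 0.3      # ms, upstroke (inward) time scale
    tau_out: float = 6.0     # ms, repolarisation (outward) time scale
    tau_open: float = 120.0  # ms, gate recovery
    tau_close: float = 120.0 # ms, gate inactivation; sets APD (~230 ms)
    u_gate: float = 0.13     # gate threshold (dimensionless)
    V_rest: float = -85.0    # mV
    amplitude: float = 105.0 # mV, voltage span (peak ≈ V_rest + amplitude)

    gate_names = ("h",)

    @property
    def V_peak(self) -> float:
        return self.V_rest + self.amplitude

    def initial_state(self, n: int):
        return (np.full(n, self.V_rest),
                {"h": np.ones(n)})

    def _du_dt(self, u, h):
        return h * u * u * (1.0 - u) / self.tau_in - u / self.tau_out

    def ionic_current(self, V, gates, stimulus=0.0):
        V = np.asarray(V, dtype=float)
        if not np.all(np.isfinite(V)):
            raise ValueError("non-finite membrane voltage")
        h = np.asarray(gates["h"], dtype=float)
        if not np.all(np.isfinite(h)):
            raise ValueError("non-finite gate state")
        u = (V - self.V_rest) / self.amplitude
        return -self.amplitude * self._du_dt(u, h) - stimulus

    def step(self, V, gates, I_total, dt):
        h = gates["h"]
        u = (V - self.V_rest) / self.amplitude
        dV = self.amplitude * self._du_dt(u, h) + I_total
        below = u < self.u_gate
        dh = np.where(below, (1.0 - h) / self.tau_open, -h / self.tau_close)
        V += dt * dV
        h += dt * dh


@dataclass
class PassiveMembrane(CellModel):
    """I_ion = 0 everywhere: pure coupling dynamics.

    Used for conservation checks and closed-form coupling tests.
    """

    V_rest: float = -85.0
    V_peak: float = 20.0
    gate_names = ()

    def initial_state(self, n: int):
        return np.full(n, self.V_rest), {}

    def ionic_current(self, V, gates, stimulus=0.0):
        V = np.asarray(V, dtype=float)
        if not np.all(np.isfinite(V)):
            raise ValueError("non-finite membrane voltage")
        return np.zeros_like(V) - stimulus

    def step(self, V, gates, I_total, dt):
        V += dt * I_total
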