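"""Thoracic artificial lung (TAL) block and its attachment modes.

The TAL is a pumpless gas-exchange device grafted onto the pulmonary artery.
Haemodynamically it is an inlet graft (R, L and a graft compliance), two
compliant blood chambers separated by flow-dependent resistances (the fibre
bundle), and two return grafts: one to the left atrium and one to the distal
pulmonary artery.  A band resistance on the native pulmonary-artery segment
between the two anastomoses divides flow between the device and the natural
lung.

Attachment modes:

* ``parallel`` - PA -> TAL -> left atrium; the distal-PA return graft is
  occluded (disabled) and the banded native path stays open.
* ``series`` - proximal PA -> TAL -> distal PA; the left-atrial return graft
  and the native segment between the anastomoses are occluded.
* ``hybrid`` - both return grafts open; the band resistance governs how much
  blood still crosses the natural lung directly.
* ``off`` - every TAL branch is disabled; the circulation is untouched.

Occlusion is modelled by removing the branch from the dynamics (flow is
identically zero) rather than by a huge resistance, which would only add
numerical stiffness.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

from .circuits import (CircuitElement, Network, capacitor, flow_resistor,
                       inductive)

__all__ = ["TALParams", "MODES", "configure_tal", "tal_flow_dependent_drop",
           "attach_tal"]

MODES = ("off", "parallel", "series", "hybrid")

#: node names introduced by the attachment
TAL_NODES = ("talin", "talad", "talap")


@dataclass(frozen=True)
class TALParams:
    """TAL block parameters (mmHg*s/ml, mmHg*s^2/ml, ml/mmHg).

    ``math.inf`` on any graft/band resistance disables that branch, which is
    how the attachment modes are realised.  ``k_ad``/``k_ap`` are the
    quadratic coefficients (mmHg*s^2/ml^2) of the flow-dependent chamber
    resistances dP = R0*Q + k*Q*|Q|.
    """

    # inlet graft (from the main pulmonary artery)
    R_in: float = 0.01
    L_in: float = 1e-4
    C_in: float = 1.5
    # inlet chamber
    C_ad: float = 2.0
    R_ad0: float = 0.02
    k_ad: float = 1e-4
    # outlet chamber
    C_ap: float = 2.0
    R_ap0: float = 0.02
    k_ap: float = 1e-4
    # left-atrial return graft
    R_ala: float = 0.09
    L_ala: float = 1e-4
    # distal pulmonary-artery return graft
    R_an: float = 0.002
    L_an: float = 1e-4
    # native pulmonary-artery band between the anastomoses
    R_pab: float = 2.0
    mode: str = "off"

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown TAL mode {self.mode!r};"
                             f" expected one of {MODES}")
        for name in ("C_in", "C_ad", "C_ap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("R_in", "R_ad0", "k_ad", "R_ap0", "k_ap", "R_ala",
                     "R_an", "R_pab"):
            v = getattr(self, name)
            if not math.isinf(v) and v < 0:
                raise ValueError(f"{name} must be >= 0 (or inf to disable)")
        for name in ("L_in", "L_ala", "L_an"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def configure_tal(params: TALParams, mode: str) -> TALParams:
    """Return a copy of ``params`` set to the given attachment mode."""
    if mode not in MODES:
        raise ValueError(f"unknown TAL mode {mode!r}; expected one of {MODES}")
    return dataclasses.replace(params, mode=mode)


def tal_flow_dependent_drop(q: float, r0: float, k: float) -> float:
    """Pressure drop of a flow-dependent resistance: R0*Q + k*Q*|Q|.

    Sign-preserving; k = 0 recovers a linear resistance.
    """
    if r0 < 0 or k < 0:
        raise ValueError("R0 and k must be >= 0")
    return r0 * q + k * q * abs(q)


def _branch_active(mode: str, branch: str) -> bool:
    table = {
        "off": (),
        "parallel": ("inlet", "ala", "band"),
        "series": ("inlet", "an"),
        "hybrid": ("inlet", "ala", "an", "band"),
    }
    return branch in table[mode]


def attach_tal(network: Network, params: TALParams) -> Network:
    """Graft the TAL onto a built circulation network.

    The inlet anastomosis is on the main pulmonary-artery node ``pam``, the
    distal return on the small pulmonary-artery node ``pas``, the left-atrial
    return on ``la``.  The band resistance is added in series with the native
    pam->pas segment.  Three storage states (graft, inlet chamber, outlet
    chamber, all referenced to intrathoracic pressure) and up to three
    inertial states are registered.  Attaching twice is an error.
    """
    if any(e.name.startswith("TAL") for e in network.elements):
        raise ValueError("a TAL is already attached to this network")
    names = {e.name for e in network.elements}
    if "Rpam" not in names:
        raise ValueError("network has no native main-pulmonary-artery branch"
                         " 'Rpam' to anastomose to")
    mode = params.mode

    native = network.element("Rpam")
    if not _branch_active(mode, "band") and mode != "off":
        # series mode: the native segment between the anastomoses is occluded
        band = dataclasses.replace(native, enabled=False)
    elif mode == "off":
        band = native
    else:
        band = dataclasses.replace(
            native,
            params={**native.params,
                    "R": native.params["R"] + params.R_pab},
        )

    def _graft(name, a, b, r, l, active):
        el = inductive(name, a, b, r, l)
        if not active:
            el = dataclasses.replace(el, enabled=False)
        return el

    def _chamber_res(name, a, b, r0, k, active):
        el = flow_resistor(name, a, b, r0, k)
        if not active:
            el = dataclasses.replace(el, enabled=False)
        return el

    inlet_on = _branch_active(mode, "inlet")
    new_elements: list[CircuitElement] = [
        capacitor("CTALin", "talin", params.C_in, ref="intrathoracic"),
        capacitor("CTALad", "talad", params.C_ad, ref="intrathoracic"),
        capacitor("CTALap", "talap", params.C_ap, ref="intrathoracic"),
        _graft("TALin", "pam", "talin", params.R_in, params.L_in, inlet_on),
        _chamber_res("TALad", "talin", "talad", params.R_ad0, params.k_ad,
                     inlet_on),
        _chamber_res("TALap", "talad", "talap", params.R_ap0, params.k_ap,
                     inlet_on),
        _graft("TALala", "talap", "la", params.R_ala, params.L_ala,
               _branch_active(mode, "ala")),
        _graft("TALan", "talap", "pas", params.R_an, params.L_an,
               _branch_active(mode, "an")),
    ]

    elements = [band if e.name == "Rpam" else e for e in network.elements]
    elements += new_elements
    aliases = dict(network.aliases)
    aliases.update({
        "PTALin": "P:talin", "PTALad": "P:talad", "PTALap": "P:talap",
        "QTALin": "Q:TALin", "QTALad": "Q:TALad", "QTALap": "Q:TALap",
        "QTALala": "Q:TALala", "QTALan": "Q:TALan",
        "VTALin": "V:CTALin", "VTALad": "V:CTALad", "VTALap": "V:CTALap",
    })
    return dataclasses.replace(network, elements=elements, aliases=aliases)
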