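"""Bundled channel and compound presets.

The compound presets are qualitative mechanism templates spanning the
micro-dynamics landscape of well-known sodium-channel inhibitors: a strongly
state-dependent compound with fast offset (riluzole-like), one with slow
onset and offset (lidocaine-like), a very fast one (benzocaine-like), a very
slow, shallow-ratio one (bupivacaine-like), and a nearly state-independent
pore blocker (TTX-like).  Dissociation constants and perfusion time constants
follow published estimates for the name-giving compounds; the association
rates are set so that the resting-state unbinding time ``1/(k_on*K_R)``
reproduces each template's characteristic micro-offset timescale.
"""

from __future__ import annotations

from .channel import CompoundMechanism, generic_fast_nav

__all__ = ["generic_fast_nav", "compound_preset", "COMPOUND_PRESETS",
           "preset_concentrations_uM"]


def _mech(name, k_on, K_R, K_I, tau):
    return CompoundMechanism(
        name=name, k_on=k_on, K_R=K_R, K_I=K_I, perfusion_tau_s=tau
    )


COMPOUND_PRESETS: dict[str, CompoundMechanism] = {
    # high K_R/K_I, fast onset, micro-offset 1/(k_on*K_I) = 5 ms
    "riluzole_like": _mech("riluzole_like", k_on=0.04, K_R=1000.0, K_I=5.0,
                           tau=13.6),
    # moderate ratio, slow onset, micro-offset ~260 ms
    "lidocaine_like": _mech("lidocaine_like", k_on=2e-4, K_R=1300.0, K_I=19.0,
                            tau=1.72),
    # very fast both ways, micro-offset ~0.5 ms
    "benzocaine_like": _mech("benzocaine_like", k_on=2.5e-2, K_R=2200.0,
                             K_I=80.0, tau=1.42),
    # slow both ways (micro-offset ~500 ms), shallow observable EIP range
    "bupivacaine_like": _mech("bupivacaine_like", k_on=1.1e-4, K_R=320.0,
                              K_I=18.0, tau=3.56),
    # nearly state-independent, kinetics fast relative to the protocol
    "ttx_like": _mech("ttx_like", k_on=30.0, K_R=0.028, K_I=0.017, tau=22.9),
}

# concentration series matching each template's potency scale (µM)
_PRESET_CONCS: dict[str, tuple[float, ...]] = {
    "riluzole_like": (10.0, 30.0, 100.0, 300.0),
    "lidocaine_like": (100.0, 300.0, 1000.0),
    "benzocaine_like": (100.0, 300.0, 1000.0),
    "bupivacaine_like": (10.0, 30.0, 100.0),
    "ttx_like": (0.03, 0.1, 0.3),
}


def compound_preset(name: str) -> CompoundMechanism:
    try:
        mech = COMPOUND_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(COMPOUND_PRESETS)}"
        ) from None
    return CompoundMechanism.from_dict(mech.to_dict())


def preset_concentrations_uM(name: str) -> tuple[float, ...]:
    compound_preset(name)  # validate name
    return _PRESET_CONCS[name]
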