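"""CAR construct definitions.

A first-generation CAR carries only the CD3zeta signalling chain; a
second-generation CAR adds the CD28 costimulatory domain, represented here
by three independent mechanisms that can be toggled individually for
ablation experiments: recruitment of the Grb2 adaptor, recruitment of the
GADS adaptor, and enhancement of LCK catalytic activity.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CARConstruct:
    generation: int = 2
    mech_grb2: bool = True
    mech_gads: bool = True
    mech_lck_boost: bool = True

    def __post_init__(self) -> None:
        if self.generation not in (1, 2):
            raise ValueError(f"generation must be 1 or 2, got {self.generation}")
        if self.generation == 1 and (
            self.mech_grb2 or self.mech_gads or self.mech_lck_boost
        ):
            raise ValueError("generation-1 constructs cannot carry CD28 mechanisms")

    @property
    def label(self) -> str:
        if self.generation == 1:
            return "gen1"
        on = [
            name
            for name, flag in (
                ("grb2", self.mech_grb2),
                ("gads", self.mech_gads),
                ("lck", self.mech_lck_boost),
            )
            if flag
        ]
        if len(on) == 3:
            return "gen2"
        if not on:
            return "gen2-none"
        return "gen2-" + "+".join(on)


GEN1 = CARConstruct(generation=1, mech_grb2=False, mech_gads=False, mech_lck_boost=False)
GEN2 = CARConstruct(generation=2, mech_grb2=True, mech_gads=True, mech_lck_boost=True)
GEN2_GRB2_ONLY = CARConstruct(2, mech_grb2=True, mech_gads=False, mech_lck_boost=False)
GEN2_GADS_ONLY = CARConstruct(2, mech_grb2=False, mech_gads=True, mech_lck_boost=False)
GEN2_LCK_ONLY = CARConstruct(2, mech_grb2=False, mech_gads=False, mech_lck_boost=True)

#: The construct panel of the mechanism-ablation experiment, in report order.
ABLATION_PANEL = (
    ("gen1", GEN1),
    ("grb2_only", GEN2_GRB2_ONLY),
    ("gads_only", GEN2_GADS_ONLY),
    ("lck_only", GEN2_LCK_ONLY),
    ("gen2_all", GEN2),
)
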