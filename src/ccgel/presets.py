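"""Figure presets: canned configurations for the model's standard scenarios.

Each preset pins only the physically stated parameters of its scenario
(Bjerrum length or solvent, salt, spring constant, valence, stiffening);
sweep grids are package defaults chosen to cover the interesting range and
can be overridden on the command line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["FIGURE_PRESETS", "FigurePreset", "get_preset"]


@dataclass(frozen=True)
class FigurePreset:
    name: str
    subcommand: str  # which CLI subcommand realises the scenario
    description: str
    params: dict = field(default_factory=dict)


_SALT_001 = ((0.01, 1), (0.01, 1))  # 1:1 salt, 0.01 M: both ion species
_SALT_0001 = ((0.001, 1), (0.001, 1))

FIGURE_PRESETS: dict[str, FigurePreset] = {
    # beq vs spring constant in the condensed regime, methanol-like solvent,
    # at two 1:1 salt concentrations.
    "fig1": FigurePreset(
        name="fig1",
        subcommand="phase",
        description=(
            "equilibrium spacing vs spring constant at lB = 1.7 nm "
            "(methanol, room T), CC branch, 0.01 M and 0.001 M 1:1 salt"
        ),
        params={
            "mode": "a-sweep",
            "bjerrum_nm": 1.7,
            "z": 1,
            "salts": (_SALT_001, _SALT_0001),
            "a_grid": ("geom", 0.02, 2.0, 60),
            "branch": "cc",
        },
    ),
    # beq vs lB for both branches; the bistable overlap shows as rows where
    # both branch columns are populated.
    "fig2": FigurePreset(
        name="fig2",
        subcommand="phase",
        description=(
            "both-branch equilibrium spacing vs Bjerrum length, "
            "a = 0.1 nm^-2, 0.01 M 1:1 salt"
        ),
        params={
            "mode": "sweep",
            "z": 1,
            "spring_a": 0.1,
            "salts": (_SALT_001,),
            "lb_grid": ("lin", 1.0, 3.5, 0.05),
        },
    ),
    # the double-well free-energy landscape in the middle of the transition
    # range.
    "fig3": FigurePreset(
        name="fig3",
        subcommand="profile",
        description=(
            "piecewise free energy g(b) at lB = 2.0 nm inside the transition "
            "range, a = 0.1 nm^-2, 0.01 M 1:1 salt"
        ),
        params={
            "bjerrum_nm": 2.0,
            "z": 1,
            "spring_a": 0.1,
            "salts": (_SALT_001,),
            "b_grid": ("lin", 0.5, 6.0, 0.005),
        },
    ),
    # overlap intervals for three spring constants: the transition funnel.
    "fig4": FigurePreset(
        name="fig4",
        subcommand="phase",
        description=(
            "bistable overlap intervals for a = 5.0, 1.0, 0.1 nm^-2, "
            "0.01 M 1:1 salt (the transition funnel)"
        ),
        params={
            "mode": "funnel",
            "z": 1,
            "salts": (_SALT_001,),
            "a_values": (5.0, 1.0, 0.1),
            "lb_bracket": (0.05, 5.0),
        },
    ),
    # passive condensation only: beq vs lB deep into poor solvents.
    "fig5": FigurePreset(
        name="fig5",
        subcommand="phase",
        description=(
            "CC-branch equilibrium spacing vs Bjerrum length out to very "
            "poor solvents, a = 0.1 nm^-2, 0.01 M 1:1 salt"
        ),
        params={
            "mode": "sweep",
            "z": 1,
            "spring_a": 0.1,
            "salts": (_SALT_001,),
            "lb_grid": ("lin", 2.0, 20.0, 0.25),
        },
    ),
    # collapse scenarios: condensed counterions stiffening the springs.
    "fig6": FigurePreset(
        name="fig6",
        subcommand="collapse",
        description=(
            "collapse curves for stiffening t = 0, 4, 50 nm^-2 "
            "(a0 = 0.1 nm^-2, 0.01 M 1:1 salt)"
        ),
        params={
            "z": 1,
            "a0": 0.1,
            "t_values": (0.0, 4.0, 50.0),
            "salts": (_SALT_001,),
            "lb_grid": ("lin", 1.0, 20.0, 0.25),
        },
    ),
}


def get_preset(name: str) -> FigurePreset:
    try:
        return FIGURE_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(FIGURE_PRESETS)}"
        ) from None
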