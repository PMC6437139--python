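"""Frozen experiment presets for the printed one- and two-gene circuits.

``fig4``–``fig8`` are the five qualitative shapes of a positive-feedback
(``H = -4``) self-regulated gene with ``K = 45`` and leakage ``0.15`` at the
burst-parameter pairs ``(a, b) = (5,10), (5,30), (10,5), (8,16), (15,20)``,
started from a Gaussian N(2, 0.1).  ``fig9``–``fig11`` are two-gene
networks — two independent copies of the ``fig4`` gene, a self/cross
activator–repressor pair, and a mutual-repression toggle switch — started
from a product Gaussian N([10,10], [1,1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .kernels import CrossFeedback2D, HillFeedback1D
from .solver import ModelND
from .stationary import Model1D

__all__ = ["Preset", "PRESETS", "get_preset"]


@dataclass(frozen=True)
class Preset:
    name: str
    model: object  # Model1D or ModelND
    ic_means: tuple[float, ...]
    ic_sds: tuple[float, ...]
    t_end: float
    n_cells: int  # per dimension default
    record: dict = field(default_factory=dict)  # printed caption parameters


def _fig1d(name: str, a: float, b: float) -> Preset:
    fb = HillFeedback1D(H=-4, K=45.0, epsilon=0.15)
    return Preset(
        name=name,
        model=Model1D(a=a, b=b, feedback=fb),
        ic_means=(2.0,),
        ic_sds=(0.1,),
        t_end=10.0,
        n_cells=1024,
        record={"H": -4, "epsilon": 0.15, "K": 45, "a": a, "b": b},
    )


def _fig9() -> Preset:
    fb1 = HillFeedback1D(H=-4, K=45.0, epsilon=0.15)
    feedback = CrossFeedback2D(variant="product_of_1d", factors=(fb1, fb1))
    model = ModelND(km=(5.0, 5.0), b=(10.0, 10.0), feedback=feedback)
    return Preset(
        name="fig9", model=model, ic_means=(10.0, 10.0), ic_sds=(1.0, 1.0),
        t_end=10.0, n_cells=96,
        record={"H_i": -4, "epsilon_i": 0.15, "K_i": 45, "a_i": 5, "b_i": 10},
    )


def _fig10() -> Preset:
    feedback = CrossFeedback2D(
        variant="general_cross",
        params=(
            {"H_self": -4, "H_cross": 2, "K_self": 45.0, "K_cross": 45.0,
             "eps1": 0.002, "eps2": 0.02, "eps3": 0.2},
            {"H_self": 2, "H_cross": -6, "K_self": 70.0, "K_cross": 70.0,
             "eps1": 0.002, "eps2": 0.1, "eps3": 0.2},
        ),
    )
    model = ModelND(km=(10.0, 20.0), b=(10.0, 20.0), feedback=feedback)
    return Preset(
        name="fig10", model=model, ic_means=(10.0, 10.0), ic_sds=(1.0, 1.0),
        t_end=10.0, n_cells=192,
        record={"H11": -4, "H21": -6, "H12": 2, "H22": 2, "K11": 45, "K12": 45,
                "K21": 70, "K22": 70, "eps11": 0.002, "eps21": 0.002,
                "eps12": 0.02, "eps22": 0.1, "eps13": 0.2, "eps23": 0.2,
                "gamma_x": 1, "gamma_m": 25, "km1": 10, "km2": 20,
                "b1": 10, "b2": 20},
    )


def _fig11() -> Preset:
    feedback = CrossFeedback2D(
        variant="mutual_repression",
        K=(45.0, 45.0), epsilon=(0.15, 0.15), H_cross=(4, 4),
    )
    model = ModelND(km=(8.0, 8.0), b=(16.0, 16.0), feedback=feedback)
    return Preset(
        name="fig11", model=model, ic_means=(10.0, 10.0), ic_sds=(1.0, 1.0),
        t_end=10.0, n_cells=128,
        record={"H12": 4, "H21": 4, "K1": 45, "K2": 45, "eps1": 0.15,
                "eps2": 0.15, "gamma_x": 1, "gamma_m": 25, "km": 8, "b": 16},
    )


PRESETS: dict[str, Preset] = {
    "fig4": _fig1d("fig4", a=5.0, b=10.0),
    "fig5": _fig1d("fig5", a=5.0, b=30.0),
    "fig6": _fig1d("fig6", a=10.0, b=5.0),
    "fig7": _fig1d("fig7", a=8.0, b=16.0),
    "fig8": _fig1d("fig8", a=15.0, b=20.0),
    "fig9": _fig9(),
    "fig10": _fig10(),
    "fig11": _fig11(),
}


def get_preset(name: str) -> Preset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
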