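"""Three-level parametrization: probe scan, RDF-bounded radii, non-radii DE.

Level 1 scans discrete water probe radii (default 0.60–1.40 Å in 0.05 Å
steps). For each probe the per-element atomic-radius boxes follow from the
first peak of the solute-atom/water-oxygen radial distribution function:
rho_element is confined to [max(floor, R_min - rho_w), R_max - rho_w], with
floors of 0.6 Å (hydrogen) and 1.0 Å (heavy atoms). Level 2A runs
differential evolution (DE) over the radii — the expensive, geometry-bearing
parameters — and, for every radii candidate, Level 2B runs an inner DE over
the geometry-free non-radii parameters (F0, F1, F2, gamma0, xi, coupling
coefficients) on cached geometry. The objective everywhere is the RMSE of
model vs reference hydration free energies on the training set.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.optimize import differential_evolution

from .assembler import energy_from_geometry, prepare_geometry
from .constants import GRID_SPACING_DEFAULT
from .model_io import Molecule, MultipoleParams, NonpolarParams, ParameterSet

#: full-scale DE settings (population, generations) for Levels 2A and 2B.
DE_DEFAULTS = {"2A": (15, 15), "2B": (30, 5000)}

_H_FLOOR = 0.6
_HEAVY_FLOOR = 1.0


def default_probe_grid() -> list[float]:
    """17 probe radii: {0.60 + 0.05 n, 0 <= n <= 16} Å."""
    return [round(0.6 + 0.05 * n, 2) for n in range(17)]


@dataclass
class BoundsConfig:
    probe_grid: list[float] = dc_field(default_factory=default_probe_grid)
    #: synthetic per-element first-RDF-peak windows (R_min, R_max), Å
    rdf_window: dict[str, tuple[float, float]] = dc_field(
        default_factory=lambda: {
            "H": (1.4, 2.4), "O": (1.6, 2.6), "N": (1.7, 2.8), "C": (2.2, 3.2),
        }
    )
    #: non-radii bounds; the defaults bracket the published NC optima >= 3x
    nonradii_bounds: dict[str, tuple[float, float]] = dc_field(
        default_factory=lambda: {
            "F0": (-0.2, 0.2),
            "F1": (-4.5, 4.5),
            "F2": (-3.0, 3.0),
            "gamma0": (0.0, 0.15),
            "xi": (0.0, 2.0),
            "g1": (-1e5, 1e5),
            "g2": (-1e8, 1e8),
            "c1": (-5e3, 5e3),
            "c2": (-1e7, 1e7),
        }
    )

    def __post_init__(self) -> None:
        for el, (lo, hi) in self.rdf_window.items():
            if not lo < hi:
                raise ValueError(f"rdf window for {el}: need R_min < R_max")
        for k, (lo, hi) in self.nonradii_bounds.items():
            if not lo < hi:
                raise ValueError(f"nonradii bound {k}: need lo < hi")


@dataclass
class FitResult:
    best_params: ParameterSet
    train_rmse: float
    history: list[float]          # best-so-far objective per generation
    seed: int
    de_config: dict

    def __post_init__(self) -> None:
        if self.train_rmse < 0:
            raise ValueError("rmse must be >= 0")


def make_bounds(probe_radius: float, cfg: BoundsConfig) -> dict[str, tuple[float, float]]:
    """Per-element atomic-radius boxes for one probe radius; errors if empty."""
    boxes = {}
    for el, (rmin, rmax) in cfg.rdf_window.items():
        floor = _H_FLOOR if el == "H" else _HEAVY_FLOOR
        lo = max(floor, rmin - probe_radius)
        hi = rmax - probe_radius
        if not lo < hi:
            raise ValueError(
                f"empty radius box for element {el} at probe {probe_radius} Å "
                f"(window {rmin}-{rmax} Å, floor {floor} Å)"
            )
        boxes[el] = (lo, hi)
    return boxes


def rmse_objective(
    params: ParameterSet,
    molecules: list[Molecule],
    references: list[float],
    grid_spacing: float = GRID_SPACING_DEFAULT,
) -> float:
    """RMSE (kcal/mol) of pipeline hydration energies vs the references."""
    if len(molecules) != len(references):
        raise ValueError("molecules and references must have equal length")
    refs = np.asarray(references, dtype=float)
    if not np.all(np.isfinite(refs)):
        raise ValueError("references must be finite")
    pred = np.array([
        energy_from_geometry(prepare_geometry(m, params, grid_spacing), params).solv_total
        for m in molecules
    ])
    return float(np.sqrt(np.mean((pred - refs) ** 2)))


# ---------------------------------------------------------------------------
# parameter vector layouts
# ---------------------------------------------------------------------------

def _nonradii_names(variant: str, elements: list[str]) -> list[str]:
    if variant == "nc":
        return ["F0", "F1", "F2", "gamma0"] + [f"xi_{el}" for el in elements]
    if variant == "wc":
        return ["F0", "F1", "F2", "gamma0", "xi", "g1", "g2", "c1", "c2"]
    raise ValueError(f"unknown variant {variant!r}")


def _params_from_vectors(
    variant: str,
    elements: list[str],
    probe: float,
    radii_vec: np.ndarray,
    nonradii_vec: np.ndarray,
    base: ParameterSet | None = None,
) -> ParameterSet:
    radii = {el: float(r) for el, r in zip(elements, radii_vec)}
    v = list(map(float, nonradii_vec))
    mp = MultipoleParams(F0=v[0], F1=v[1], F2=v[2])
    if variant == "nc":
        xi = {el: v[4 + i] for i, el in enumerate(elements)}
        npp = NonpolarParams(gamma0=v[3], xi_by_element=xi, probe_radius=probe,
                             coupling="none")
    else:
        npp = NonpolarParams(gamma0=v[3], xi_by_element={"*": v[4]},
                             probe_radius=probe, coupling="quartic",
                             g1=v[5], g2=v[6], c1=v[7], c2=v[8])
    ps = ParameterSet(radii_by_element=radii, probe_radius=probe,
                      multipole=mp, nonpolar=npp, label=variant if variant == "nc" else "custom")
    if base is not None:
        ps.element_lj = dict(base.element_lj)
        ps.water_lj = tuple(base.water_lj)
    return ps


def _nonradii_box(variant: str, elements: list[str], cfg: BoundsConfig):
    b = cfg.nonradii_bounds
    names = _nonradii_names(variant, elements)
    return [b[n.split("_")[0] if n.startswith("xi") else n] for n in names]


def fit_nonradii(
    molecules: list[Molecule],
    references: list[float],
    variant: str,
    probe_radius: float,
    radii_by_element: dict[str, float],
    cfg: BoundsConfig,
    popsize: int = 30,
    generations: int = 5000,
    seed: int = 0,
    grid_spacing: float = GRID_SPACING_DEFAULT,
    base: ParameterSet | None = None,
) -> FitResult:
    """Level 2B: DE over the non-radii parameters on fixed, cached geometry."""
    elements = sorted(radii_by_element)
    probe_params = _params_from_vectors(
        variant, elements, probe_radius,
        np.array([radii_by_element[el] for el in elements]),
        np.zeros(len(_nonradii_names(variant, elements))), base,
    )
    geos = [prepare_geometry(m, probe_params, grid_spacing) for m in molecules]
    refs = np.asarray(references, dtype=float)
    box = _nonradii_box(variant, elements, cfg)
    radii_vec = np.array([radii_by_element[el] for el in elements])

    def objective(vec):
        ps = _params_from_vectors(variant, elements, probe_radius, radii_vec, vec, base)
        pred = np.array([energy_from_geometry(g, ps).solv_total for g in geos])
        return float(np.sqrt(np.mean((pred - refs) ** 2)))

    history: list[float] = []

    def track(xk, convergence=None):
        val = objective(np.asarray(xk))
        history.append(min(history[-1], val) if history else val)

    res = differential_evolution(
        objective, bounds=box, popsize=popsize, maxiter=generations,
        seed=seed, tol=1e-12, polish=True, callback=track,
    )
    best = _params_from_vectors(variant, elements, probe_radius, radii_vec, res.x, base)
    history.append(min(history[-1], float(res.fun)) if history else float(res.fun))
    return FitResult(
        best_params=best, train_rmse=float(res.fun), history=history, seed=seed,
        de_config={"2B": (popsize, generations)},
    )


def fit(
    molecules: list[Molecule],
    references: list[float],
    variant: str,
    cfg: BoundsConfig | None = None,
    pop2a: int = 15,
    gen2a: int = 15,
    pop2b: int = 30,
    gen2b: int = 5000,
    seed: int = 0,
    grid_spacing: float = GRID_SPACING_DEFAULT,
    base: ParameterSet | None = None,
) -> FitResult:
    """Full nested parametrization (probe scan / radii DE / non-radii DE).

    Reproducible for a fixed seed: every DE instance draws its seed from a
    spawned child of ``seed``. Returns the global best over the probe grid.
    """
    if len(molecules) < 2:
        raise ValueError("need at least two training molecules")
    cfg = cfg or BoundsConfig()
    elements = sorted({a.element for m in molecules for a in m.atoms})
    ss = np.random.SeedSequence(seed)
    best: FitResult | None = None
    history: list[float] = []

    for probe, child in zip(cfg.probe_grid, ss.spawn(len(cfg.probe_grid))):
        boxes = make_bounds(probe, cfg)
        radii_box = [boxes[el] for el in elements]
        seed_2a, seed_2b = (int(s.generate_state(1)[0] % 2**31) for s in child.spawn(2))
        inner_best: dict = {}

        def objective_2a(radii_vec):
            radii = {el: float(r) for el, r in zip(elements, radii_vec)}
            sub = fit_nonradii(
                molecules, references, variant, probe, radii, cfg,
                popsize=pop2b, generations=gen2b, seed=seed_2b,
                grid_spacing=grid_spacing, base=base,
            )
            if not inner_best or sub.train_rmse < inner_best["rmse"]:
                inner_best.update(rmse=sub.train_rmse, params=sub.best_params)
            history.append(min(history[-1], sub.train_rmse) if history else sub.train_rmse)
            return sub.train_rmse

        differential_evolution(
            objective_2a, bounds=radii_box, popsize=pop2a, maxiter=gen2a,
            seed=seed_2a, tol=1e-12, polish=False,
        )
        if best is None or inner_best["rmse"] < best.train_rmse:
            best = FitResult(
                best_params=inner_best["params"],
                train_rmse=inner_best["rmse"],
                history=list(history),
                seed=seed,
                de_config={"2A": (pop2a, gen2a), "2B": (pop2b, gen2b)},
            )
    assert best is not None
    best.history = history
    return best


def balanced_rerank(
    candidates: list[FitResult],
    aux_molecules: list[Molecule],
    aux_references: list[float],
    weight: float = 1.0,
    grid_spacing: float = GRID_SPACING_DEFAULT,
) -> FitResult:
    """Rerank fit outcomes by train RMSE + weight * auxiliary-set RMSE.

    The auxiliary set plays the role of a second chemistry (amino-acid
    analogues) weighted equally with the training molecules; ties keep the
    first candidate in input order.
    """
    if not candidates:
        raise ValueError("no candidates to rerank")
    if not aux_molecules:
        raise ValueError("auxiliary set must be non-empty")
    combined = [
        c.train_rmse + weight * rmse_objective(
            c.best_params, aux_molecules, aux_references, grid_spacing
        )
        for c in candidates
    ]
    return candidates[int(np.argmin(combined))]
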