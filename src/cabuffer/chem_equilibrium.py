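"""Equilibrium speciation of Ca2+/Mg2+ chelator solutions.

Computes free-ion concentrations in calibration-solution recipes containing
EGTA and/or fura-2 at a fixed, buffered pH.  The model is standard
mass-action chemistry: each chelator ``L`` binds protons stepwise
(``H+ + H_{n-1}L <-> H_nL``) and the metals at the unprotonated site
(``Ca2+ + L <-> CaL``, ``Mg2+ + L <-> MgL``).  Protonated metal complexes
(CaHL, MgHL) are negligible near neutral pH and are not modelled.

Stability constants are shipped as a versioned table of critical values
(NIST/Martell-Smith style, 20 deg C, I = 0.1 M reference) and corrected to
the working conditions by

* the Davies equation for ionic strength (single-parameter extension of
  Debye-Hueckel, valid to roughly I = 0.5 M), and
* the van't Hoff relation for temperature, using tabulated reaction
  enthalpies.

pH is treated as an activity reading (what a pH meter reports) and converted
to a proton concentration through the Davies single-ion activity
coefficient, following common practice in Ca2+-buffer calculators.

Inert electrolytes (K+, Na+, Cl-, HEPES) enter only through the ionic
strength.  The proton balance is not solved: pH is fixed by the buffer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "CONSTANTS_VERSION",
    "LIGANDS",
    "SolutionComposition",
    "SpeciationResult",
    "UnsupportedLigandError",
    "SpeciationError",
    "apparent_kd",
    "solve_free_ca",
]

# --------------------------------------------------------------------------
# constants table
# --------------------------------------------------------------------------

CONSTANTS_VERSION = "critical-2024.1 (20 degC, I=0.1 M molar reference)"

#: Gas constant, kJ mol^-1 K^-1.
_R = 8.314e-3

#: Debye-Hueckel A parameter near room temperature (kg^1/2 mol^-1/2).
_DAVIES_A = 0.51

_T_REF_C = 20.0
_I_REF = 0.1


@dataclass(frozen=True)
class _LigandConstants:
    """Critical stability constants for one chelator (log10, association)."""

    charge: int                      # charge of the fully deprotonated anion
    log_k_h: tuple[float, ...]       # stepwise protonation constants
    dh_h: tuple[float, ...]          # reaction enthalpies, kJ/mol
    log_k_ca: float
    dh_ca: float
    log_k_mg: float
    dh_mg: float


# EGTA: Martell & Smith critical values, 20 degC, 0.1 M.
# fura-2: BAPTA-family constants consistent with the reported ~0.14 uM Kd
# (20 degC, 0.1 M) and weak protonation (highest pKa ~6.4).
LIGANDS: dict[str, _LigandConstants] = {
    "EGTA": _LigandConstants(
        charge=-4,
        log_k_h=(9.47, 8.85, 2.66, 2.00),
        dh_h=(-23.4, -23.0, 0.0, 0.0),
        log_k_ca=10.97,
        dh_ca=-33.3,
        log_k_mg=5.21,
        dh_mg=21.5,
    ),
    "fura-2": _LigandConstants(
        charge=-5,
        log_k_h=(6.40, 5.50),
        dh_h=(0.0, 0.0),
        log_k_ca=6.96,
        dh_ca=0.0,
        log_k_mg=2.00,
        dh_mg=0.0,
    ),
}

_LIGAND_ALIASES = {
    "egta": "EGTA",
    "fura-2": "fura-2",
    "fura2": "fura-2",
    "fura": "fura-2",
}

# Compound -> (element, stoichiometry, [(ion charge, count), ...]) used for
# totals and for the ionic-strength estimate.  HEPES is a zwitterion and
# treated as ionically silent; hydroxides are assumed neutralised (pH is
# buffered), contributing only their cation.
_COMPOUNDS: dict[str, dict] = {
    "KCl": {"ions": [(1, 1), (-1, 1)]},
    "NaCl": {"ions": [(1, 1), (-1, 1)]},
    "KOH": {"ions": [(1, 1)]},
    "NaOH": {"ions": [(1, 1)]},
    "HCl": {"ions": [(-1, 1)]},
    "HEPES": {"ions": []},
    "CaCl2": {"metal": "Ca", "ions": [(2, 1), (-1, 2)]},
    "MgCl2": {"metal": "Mg", "ions": [(2, 1), (-1, 2)]},
    "CaCO3": {"metal": "Ca", "ions": [(2, 1)]},
    "EGTA": {"ligand": "EGTA"},
    "fura-2": {"ligand": "fura-2"},
}


class UnsupportedLigandError(ValueError):
    """Raised for a chelator not present in the constants table."""


class SpeciationError(RuntimeError):
    """Raised when the equilibrium solver fails to reach its residual."""


# --------------------------------------------------------------------------
# activity / condition corrections
# --------------------------------------------------------------------------

def _davies_log_gamma(ionic_strength: float, charge: int = 1) -> float:
    """log10 single-ion activity coefficient from the Davies equation."""
    s = math.sqrt(ionic_strength)
    return -_DAVIES_A * charge ** 2 * (s / (1.0 + s) - 0.3 * ionic_strength)


def _condition_log_k(
    log_k_ref: float,
    dh: float,
    dz2: float,
    ionic_strength: float,
    temperature_c: float,
) -> float:
    """Correct a reference log K to the working I and T.

    ``dz2`` is sum(z^2, reactants) - sum(z^2, products) of the association
    reaction; positive for ordinary metal/proton binding, so constants
    decrease as ionic strength screens the charges.
    """
    f = _davies_log_gamma(ionic_strength) - _davies_log_gamma(_I_REF)
    log_k = log_k_ref + dz2 * f
    t_ref = _T_REF_C + 273.15
    t = temperature_c + 273.15
    log_k += (-dh / (_R * math.log(10.0))) * (1.0 / t - 1.0 / t_ref)
    return log_k


def _ligand_effective_constants(
    lig: _LigandConstants, ph: float, temperature_c: float, ionic_strength: float
) -> tuple[float, float, float, float]:
    """Return (alpha_H, K_Ca, K_Mg, [H+]) on the concentration scale.

    ``alpha_H = [L_total,free]/[L]`` is the proton side-reaction coefficient;
    ``K_Ca``/``K_Mg`` are association constants for the bare anion.
    """
    h = 10.0 ** (-ph) / 10.0 ** _davies_log_gamma(ionic_strength)
    alpha = 1.0
    cumulative = 1.0
    z = lig.charge
    for log_k, dh in zip(lig.log_k_h, lig.dh_h):
        dz2 = (z ** 2 + 1) - (z + 1) ** 2
        k = 10.0 ** _condition_log_k(log_k, dh, dz2, ionic_strength, temperature_c)
        cumulative *= k * h
        alpha += cumulative
        z += 1
    dz2_m = (lig.charge ** 2 + 4) - (lig.charge + 2) ** 2
    k_ca = 10.0 ** _condition_log_k(lig.log_k_ca, lig.dh_ca, dz2_m, ionic_strength, temperature_c)
    k_mg = 10.0 ** _condition_log_k(lig.log_k_mg, lig.dh_mg, dz2_m, ionic_strength, temperature_c)
    return alpha, k_ca, k_mg, h


def _resolve_ligand(name: str) -> str:
    key = _LIGAND_ALIASES.get(name.strip().lower().replace("_", "-"))
    if key is None:
        raise UnsupportedLigandError(
            f"no stability constants for chelator {name!r}; known: "
            + ", ".join(sorted(LIGANDS))
        )
    return key


def apparent_kd(
    chelator: str,
    ph: float,
    temperature_c: float = 22.0,
    ionic_strength: float = 0.15,
) -> float:
    """Apparent (pH-conditional) Ca2+ dissociation constant, in uM.

    ``Kd_app = alpha_H / K_Ca`` with ``alpha_H = 1 + [H]/K_H1 +
    [H]^2/(K_H1*K_H2) + ...`` evaluated at the working pH, temperature and
    ionic strength.  Strictly decreasing in pH over the supported range.

    Parameters
    ----------
    chelator:
        ``"EGTA"`` or ``"fura-2"``.
    ph:
        Meter pH (activity scale), in [5, 10].
    temperature_c, ionic_strength:
        Working temperature (deg C) and ionic strength (M).
    """
    if not 5.0 <= ph <= 10.0:
        raise ValueError(f"pH {ph} outside supported range [5, 10]")
    if ionic_strength <= 0 or ionic_strength > 0.5:
        raise ValueError("ionic strength must be in (0, 0.5] M for Davies")
    lig = LIGANDS[_resolve_ligand(chelator)]
    alpha, k_ca, _, _ = _ligand_effective_constants(lig, ph, temperature_c, ionic_strength)
    return alpha / k_ca * 1e6


# --------------------------------------------------------------------------
# solution composition
# --------------------------------------------------------------------------

@dataclass
class SolutionComposition:
    """A calibration-solution recipe.

    Parameters
    ----------
    compounds:
        Map of compound name to total concentration in mM (non-negative).
        Recognised names: KCl, NaCl, KOH, NaOH, HCl, HEPES, CaCl2, MgCl2,
        CaCO3, EGTA, fura-2.
    ph:
        Buffered pH of the solution (fixed; no proton balance solved).
    temperature_c:
        Working temperature in deg C.
    ionic_strength:
        Ionic strength in M; if omitted, estimated from the composition
        (fully dissociated inert salts, chelators at their dominant
        protonation state).
    """

    compounds: dict[str, float]
    ph: float = 7.2
    temperature_c: float = 22.0
    ionic_strength: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.ph) or not 0.0 <= self.ph <= 14.0:
            raise ValueError(f"pH must be finite and in [0, 14], got {self.ph}")
        for name, conc in self.compounds.items():
            if name not in _COMPOUNDS and _LIGAND_ALIASES.get(
                name.strip().lower().replace("_", "-")
            ) is None:
                raise ValueError(f"unknown compound {name!r}")
            if conc < 0:
                raise ValueError(f"negative total for {name!r}: {conc}")

    # -- totals ------------------------------------------------------------

    def _entry(self, name: str) -> dict:
        if name in _COMPOUNDS:
            return _COMPOUNDS[name]
        return {"ligand": _resolve_ligand(name)}

    def metal_totals_mM(self) -> dict[str, float]:
        totals = {"Ca": 0.0, "Mg": 0.0}
        for name, conc in self.compounds.items():
            metal = self._entry(name).get("metal")
            if metal:
                totals[metal] += conc
        return totals

    def ligand_totals_mM(self) -> dict[str, float]:
        totals: dict[str, float] = {}
        for name, conc in self.compounds.items():
            lig = self._entry(name).get("ligand")
            if lig:
                totals[lig] = totals.get(lig, 0.0) + conc
        return totals

    def estimate_ionic_strength(self) -> float:
        """Rough I (M) from composition: 0.5 * sum(c_i z_i^2).

        Inert salts are counted fully dissociated; Ca/Mg at their totals;
        each chelator at the charge of its dominant protonation state at
        this pH (metal binding ignored at this stage).
        """
        contrib = 0.0  # in mM
        for name, conc in self.compounds.items():
            entry = self._entry(name)
            for charge, count in entry.get("ions", []):
                contrib += conc * count * charge ** 2
            lig_name = entry.get("ligand")
            if lig_name:
                lig = LIGANDS[lig_name]
                # dominant protonation state at pH with reference constants
                n_bound = sum(1 for pk in lig.log_k_h if pk > self.ph)
                z = lig.charge + n_bound
                contrib += conc * z ** 2
        return 0.5 * contrib * 1e-3


@dataclass
class SpeciationResult:
    """Equilibrium species of a solved calibration solution.

    ``free_ca_uM``/``free_mg_mM`` are free-ion concentrations; ``chelators``
    maps ligand name to its species in mM (``free`` is the sum over all
    protonation states of metal-free ligand, ``protonated`` the sum over
    states carrying at least one proton); ``apparent_kd_uM`` gives each
    chelator's pH-conditional Ca2+ dissociation constant under the solved
    conditions.
    """

    free_ca_uM: float
    free_mg_mM: float
    chelators: dict[str, dict[str, float]]
    apparent_kd_uM: dict[str, float]
    ionic_strength: float
    residual: float
    composition: SolutionComposition = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "free_ca_uM": self.free_ca_uM,
            "free_mg_mM": self.free_mg_mM,
            "chelators_mM": self.chelators,
            "apparent_kd_uM": self.apparent_kd_uM,
            "ionic_strength_M": self.ionic_strength,
            "residual": self.residual,
        }


# --------------------------------------------------------------------------
# solver
# --------------------------------------------------------------------------

def solve_free_ca(
    solution: SolutionComposition,
    purity: float = 1.0,
    tol: float = 1e-13,
) -> SpeciationResult:
    """Solve the coupled Ca/Mg/chelator mass-action + mass-balance system.

    Parameters
    ----------
    solution:
        Recipe with totals in mM and a buffered pH.
    purity:
        Multiplicative purity factor in (0, 1] applied to all chelator
        totals (commercial EGTA is typically 0.92-0.98 pure; default 1.0).
    tol:
        Target relative residual of the mass balances.

    Returns
    -------
    SpeciationResult
        Free ions, chelator species, per-chelator apparent Kd.  Mass
        conservation holds to better than 1e-9 relative (enforced).
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {purity}")

    ionic = solution.ionic_strength
    if ionic is None:
        ionic = solution.estimate_ionic_strength()
    if ionic <= 0:
        ionic = 1e-4  # pure-water limit guard

    metals = solution.metal_totals_mM()
    ca_t = metals["Ca"] * 1e-3  # M
    mg_t = metals["Mg"] * 1e-3
    lig_totals = {
        name: conc * 1e-3 * purity for name, conc in solution.ligand_totals_mM().items()
    }
    lig_names = [name for name, c in lig_totals.items() if c > 0]

    consts = {
        name: _ligand_effective_constants(
            LIGANDS[name], solution.ph, solution.temperature_c, ionic
        )
        for name in lig_names
    }
    kd_app = {name: consts[name][0] / consts[name][1] * 1e6 for name in lig_names}

    # Unknowns in log10: free Ca, free Mg, free (unprotonated) ligand each.
    # Zero totals are held out of the system and reported as 0.
    has_ca, has_mg = ca_t > 0, mg_t > 0

    def species(free_ca, free_mg, lig_free):
        """Per-ligand bound/protonated species from free concentrations."""
        out = {}
        for name in lig_names:
            alpha, k_ca, k_mg, _ = consts[name]
            l_free = lig_free[name]
            out[name] = {
                "free_total": l_free * alpha,
                "unprotonated": l_free,
                "protonated": l_free * (alpha - 1.0),
                "ca_bound": k_ca * free_ca * l_free,
                "mg_bound": k_mg * free_mg * l_free,
            }
        return out

    unknowns: list[str] = []
    if has_ca:
        unknowns.append("Ca")
    if has_mg:
        unknowns.append("Mg")
    unknowns += lig_names

    if unknowns:
        def residuals(x):
            vals = dict(zip(unknowns, 10.0 ** x))
            free_ca = vals.get("Ca", 0.0)
            free_mg = vals.get("Mg", 0.0)
            lig_free = {name: vals[name] for name in lig_names}
            sp = species(free_ca, free_mg, lig_free)
            res = []
            if has_ca:
                bound = sum(s["ca_bound"] for s in sp.values())
                res.append((free_ca + bound) / ca_t - 1.0)
            if has_mg:
                bound = sum(s["mg_bound"] for s in sp.values())
                res.append((free_mg + bound) / mg_t - 1.0)
            for name in lig_names:
                s = sp[name]
                total = s["free_total"] + s["ca_bound"] + s["mg_bound"]
                res.append(total / lig_totals[name] - 1.0)
            return res

        # starting point: metals mostly bound if chelator in excess
        x0 = []
        total_lig = sum(lig_totals.values())
        if has_ca:
            x0.append(math.log10(ca_t * (1e-4 if total_lig > ca_t else 0.5)))
        if has_mg:
            x0.append(math.log10(mg_t * 0.5))
        for name in lig_names:
            alpha = consts[name][0]
            x0.append(math.log10(max(lig_totals[name] / alpha * 1e-2, 1e-30)))

        sol = optimize.root(residuals, x0, method="hybr", tol=tol)
        resid = float(np.max(np.abs(residuals(sol.x))))
        if resid > 1e-9:
            # retry from an alternative start before giving up
            sol = optimize.root(residuals, np.array(x0) + 2.0, method="hybr", tol=tol)
            resid = float(np.max(np.abs(residuals(sol.x))))
        if resid > 1e-9:
            raise SpeciationError(
                f"equilibrium solver did not converge (relative residual {resid:.3e})"
            )
        vals = dict(zip(unknowns, 10.0 ** sol.x))
    else:
        vals, resid = {}, 0.0

    free_ca = vals.get("Ca", 0.0)
    free_mg = vals.get("Mg", 0.0)
    sp = species(free_ca, free_mg, {n: vals[n] for n in lig_names})

    chelators = {
        name: {
            "free": s["free_total"] * 1e3,
            "protonated": s["protonated"] * 1e3,
            "ca_bound": s["ca_bound"] * 1e3,
            "mg_bound": s["mg_bound"] * 1e3,
        }
        for name, s in sp.items()
    }

    return SpeciationResult(
        free_ca_uM=free_ca * 1e6,
        free_mg_mM=free_mg * 1e3,
        chelators=chelators,
        apparent_kd_uM=kd_app,
        ionic_strength=ionic,
        residual=resid,
        composition=solution,
    )
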