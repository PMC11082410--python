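"""Proton bookkeeping and membrane-transport thermodynamics.

Two small, exact calculators:

* a net-H+/CO2 ledger per reprogrammed metabolism (bundled as a TSV table)
  and the ATP-pathway proton balance — fermentative (Warburg) ATP production
  is pH neutral per ATP, respiration consumes one H+ per ATP, and every ATP
  hydrolysis releases one H+;

* electrochemical free energies for ion transport,
  ``dG = Z F V + R T ln(c_dest / c_origin)`` (for H+ the ratio is
  ``10^-pH_dest / 10^-pH_origin``), the electrically cancelling Na+/H+
  antiport combination, and the two-compartment sodium model that estimates
  the intracellular sodium concentration of a tumour from the
  cancer-to-normal total-sodium ratio k.

Temperature defaults to 310 K; energies are reported in J/mol and, where a
single printed figure is wanted, rounded to the nearest joule.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "ProtonYield",
    "TransportSpec",
    "SodiumModel",
    "proton_ledger",
    "net_protons",
    "atp_pathway_balance",
    "transport_deltaG",
    "h_transport_deltaG",
    "coupled_exchange_deltaG",
    "solve_cancer_isc",
    "feasibility",
]

FARADAY = 96485.3  # C/mol
GAS_CONSTANT = 8.31  # J/(mol K), two-decimal convention used throughout


@dataclass(frozen=True)
class ProtonYield:
    """Net protons and CO2 released per product unit of one pathway."""

    rm: str
    h_plus: int
    co2: int
    per_unit: str
    conditional: bool = False
    h_plus_alt: int | None = None  # second value of "0 or +1" entries

    @property
    def h_plus_range(self) -> tuple[int, int]:
        if self.conditional and self.h_plus_alt is not None:
            return (self.h_plus, self.h_plus_alt)
        return (self.h_plus, self.h_plus)


@dataclass(frozen=True)
class TransportSpec:
    """One ion moved across a membrane, origin -> destination.

    Concentrations in mmol/l (any common unit; only the ratio matters).
    ``V`` is the transmembrane potential seen by the moving charge, volts.
    """

    charge: int
    membrane_potential: float
    conc_origin: float
    conc_dest: float
    temperature: float = 310.0
    gas_constant: float = GAS_CONSTANT
    faraday: float = FARADAY

    def __post_init__(self) -> None:
        if self.conc_origin <= 0 or self.conc_dest <= 0:
            raise ValueError("concentrations must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class SodiumModel:
    """Two-compartment (extracellular/intracellular) tissue sodium model."""

    esc: float = 140.0  # extracellular sodium, mmol/l
    isc_normal: float = 12.0  # normal intracellular sodium, mmol/l
    k: float = 2.0  # cancer-to-normal total-sodium ratio
    vol_extracellular: float = 0.2
    vol_intracellular: float = 0.8

    def __post_init__(self) -> None:
        if abs(self.vol_extracellular + self.vol_intracellular - 1.0) > 1e-9:
            raise ValueError("volume fractions must sum to 1")
        if not 2.0 <= self.k <= 3.0:
            warnings.warn(
                f"k={self.k} outside the reported 2-3 fold range", stacklevel=2
            )

    @property
    def tsc_normal(self) -> float:
        """Volume-weighted total sodium of the normal tissue, mmol/l."""
        return self.vol_extracellular * self.esc + self.vol_intracellular * self.isc_normal


# --------------------------------------------------------------------------
# proton ledger
# --------------------------------------------------------------------------

def proton_ledger() -> dict[str, ProtonYield]:
    """The bundled per-RM net-proton/CO2 table."""
    text = resources.files("fentonflux.data").joinpath("proton_ledger.tsv").read_text()
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
    ledger: dict[str, ProtonYield] = {}
    for _, row in df.iterrows():
        conditional = row["conditional"] == "yes"
        alt = row.get("h_plus_alt")
        ledger[row["rm"]] = ProtonYield(
            rm=row["rm"],
            h_plus=int(row["h_plus"]),
            co2=int(row["co2"]),
            per_unit=row["per_unit"],
            conditional=conditional,
            h_plus_alt=int(alt) if conditional and isinstance(alt, str) and alt else None,
        )
    return ledger


def net_protons(rm_name: str) -> ProtonYield:
    """Exact ledger entry for one RM; unknown names list the valid ones."""
    ledger = proton_ledger()
    try:
        return ledger[rm_name]
    except KeyError:
        raise KeyError(
            f"unknown RM {rm_name!r}; ledger entries: {sorted(ledger)}"
        ) from None


def atp_pathway_balance(production: str, hydrolysis_events: int) -> int:
    """Net H+ per ATP cycle for a production pathway plus hydrolyses.

    Fermentation (Warburg) is pH neutral per ATP produced; respiration
    consumes one H+ per ATP; each hydrolysis releases one H+.
    """
    if hydrolysis_events < 0:
        raise ValueError("hydrolysis_events must be >= 0")
    per_atp = {"warburg": 0, "respiration": -1, "none": 0}
    try:
        production_h = per_atp[production]
    except KeyError:
        raise ValueError(
            f"production must be one of {sorted(per_atp)}, got {production!r}"
        ) from None
    return production_h + hydrolysis_events


# --------------------------------------------------------------------------
# transport free energies
# --------------------------------------------------------------------------

def transport_deltaG(spec: TransportSpec) -> float:
    """dG = Z F V + R T ln(c_dest / c_origin), in J/mol."""
    electrical = spec.charge * spec.faraday * spec.membrane_potential
    chemical = spec.gas_constant * spec.temperature * math.log(
        spec.conc_dest / spec.conc_origin
    )
    return electrical + chemical


def h_transport_deltaG(
    ph_origin: float,
    ph_dest: float,
    membrane_potential: float,
    temperature: float = 310.0,
) -> float:
    """Proton-transport dG with concentrations given as pH values."""
    spec = TransportSpec(
        charge=1,
        membrane_potential=membrane_potential,
        conc_origin=10.0**-ph_origin,
        conc_dest=10.0**-ph_dest,
        temperature=temperature,
    )
    return transport_deltaG(spec)


def coupled_exchange_deltaG(na: TransportSpec, h: TransportSpec) -> float:
    """Total dG of an electroneutral 1:1 antiport; electrical terms cancel.

    Requires the two legs to see opposite potentials across the same
    membrane (``na.V == -h.V``); the result is then
    ``R T [ln(na ratio) + ln(h ratio)]``, independent of V.
    """
    if abs(na.membrane_potential + h.membrane_potential) > 1e-12:
        raise ValueError("antiport legs must satisfy na.V == -h.V")
    if (na.gas_constant, na.temperature) != (h.gas_constant, h.temperature):
        raise ValueError("both legs must share R and T")
    rt = na.gas_constant * na.temperature
    return rt * (
        math.log(na.conc_dest / na.conc_origin)
        + math.log(h.conc_dest / h.conc_origin)
    )


def solve_cancer_isc(model: SodiumModel) -> float:
    """Intracellular sodium of the tumour implied by TSC_C = k * TSC_N.

    Solves ``k * TSC_N = v_e * ESC + v_i * ISC_C`` for ISC_C (mmol/l),
    holding the extracellular concentration fixed.
    """
    if model.vol_intracellular == 0:
        raise ValueError("intracellular volume fraction must be nonzero")
    return (model.k * model.tsc_normal - model.vol_extracellular * model.esc) / (
        model.vol_intracellular
    )


def feasibility(deltaG: float) -> str:
    """'feasible' (dG < 0), 'infeasible' (dG > 0) or 'marginal' (dG == 0)."""
    if not math.isfinite(deltaG):
        raise ValueError("deltaG must be finite")
    if deltaG > 0:
        return "infeasible"
    if deltaG < 0:
        return "feasible"
    return "marginal"
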