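"""Factor-graph metabolic maps.

A map is a bipartite graph of metabolite pools and reaction modules.  Each
module carries the genes whose expression is used to estimate its flux, a set
of metabolites it consumes and a set it produces.  Flux balance is imposed
only on the pools listed in ``balanced_set`` (pools with both producers and
consumers); terminal products are left free.

The bundled default (:func:`default_map`) is a curated cytosolic iron / ROS
map with 15 modules: three sources feeding the cytosolic Fe2+ pool, four
sinks draining it (Fe-S cluster synthesis, heme synthesis, Fe2+ export and
the Fenton reaction), ferritin storage of the Fe3+ produced by the Fenton
reaction, and seven superoxide / hydrogen-peroxide source-sink modules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ReactionModule",
    "MetabolicMap",
    "MapSchemaError",
    "load_map",
    "write_map",
    "default_map",
    "FENTON_MODULE",
]

#: Name of the Fenton-reaction module in the bundled map.
FENTON_MODULE = "Fenton reaction"


class MapSchemaError(ValueError):
    """A map definition violated the schema; the message names the record."""


@dataclass
class ReactionModule:
    """One metabolic branch, modelled downstream as a small neural network."""

    name: str
    genes: list[str]
    consumes: list[str] = field(default_factory=list)
    produces: list[str] = field(default_factory=list)
    direction_note: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise MapSchemaError("module with empty name")
        if not self.genes:
            raise MapSchemaError(f"module {self.name!r} has no genes")


@dataclass
class MetabolicMap:
    """Bipartite factor graph of metabolite pools and reaction modules."""

    metabolites: list[str]
    modules: list[ReactionModule]
    balanced_set: list[str]
    name: str = "metabolic map"
    description: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        seen_mets = set()
        for met in self.metabolites:
            if met in seen_mets:
                raise MapSchemaError(f"duplicate metabolite {met!r}")
            seen_mets.add(met)
        seen_mods = set()
        for mod in self.modules:
            if mod.name in seen_mods:
                raise MapSchemaError(f"duplicate module {mod.name!r}")
            seen_mods.add(mod.name)
            for met in list(mod.consumes) + list(mod.produces):
                if met not in seen_mets:
                    raise MapSchemaError(
                        f"module {mod.name!r} references undeclared metabolite {met!r}"
                    )
        for met in self.balanced_set:
            if met not in seen_mets:
                raise MapSchemaError(f"balanced_set references unknown metabolite {met!r}")
            producers, consumers = self.fin_fout(met)
            if not producers or not consumers:
                raise MapSchemaError(
                    f"balanced metabolite {met!r} needs >=1 producer and >=1 consumer"
                )

    # -- accessors -------------------------------------------------------
    @property
    def module_names(self) -> list[str]:
        return [m.name for m in self.modules]

    def module(self, name: str) -> ReactionModule:
        for m in self.modules:
            if m.name == name:
                return m
        raise KeyError(f"unknown module {name!r}")

    def genes(self) -> list[str]:
        """All member genes across modules, deduplicated, insertion order."""
        out: list[str] = []
        seen = set()
        for mod in self.modules:
            for g in mod.genes:
                if g not in seen:
                    seen.add(g)
                    out.append(g)
        return out

    def fin_fout(self, metabolite: str) -> tuple[list[str], list[str]]:
        """Producer and consumer module names for one metabolite pool.

        Returns ``(F_in, F_out)``: the modules whose flux enters the pool and
        the modules that drain it.  Either may be empty for terminal pools.
        """
        if metabolite not in self.metabolites:
            raise KeyError(f"unknown metabolite {metabolite!r}")
        producers = [m.name for m in self.modules if metabolite in m.produces]
        consumers = [m.name for m in self.modules if metabolite in m.consumes]
        return producers, consumers

    def stoichiometry_matrix(self, balanced_only: bool = False) -> pd.DataFrame:
        """Signed incidence matrix, metabolites x modules.

        +1 where a module produces the row metabolite, -1 where it consumes
        it, 0 otherwise.  With ``balanced_only`` the rows are restricted to
        ``balanced_set`` (the slice penalised by the flux-imbalance loss).
        """
        rows = list(self.balanced_set) if balanced_only else list(self.metabolites)
        S = np.zeros((len(rows), len(self.modules)))
        idx = {met: i for i, met in enumerate(rows)}
        for j, mod in enumerate(self.modules):
            for met in mod.produces:
                if met in idx:
                    S[idx[met], j] += 1.0
            for met in mod.consumes:
                if met in idx:
                    S[idx[met], j] -= 1.0
        return pd.DataFrame(S, index=rows, columns=self.module_names)

    def iron_outflux_modules(self) -> list[str]:
        """The five cytosolic-iron outflux modules of the default map.

        These are the consumers of "cytosolic Fe2+" plus the consumers of
        "cytosolic Fe3+" (ferritin storage of the oxidised product) — the
        denominator of the relative Fenton level.
        """
        out: list[str] = []
        for met in ("cytosolic Fe2+", "cytosolic Fe3+"):
            if met in self.metabolites:
                out.extend(self.fin_fout(met)[1])
        return out

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "description": self.description,
            "metabolites": list(self.metabolites),
            "balanced_set": list(self.balanced_set),
            "modules": [
                {
                    "name": m.name,
                    "genes": list(m.genes),
                    "consumes": list(m.consumes),
                    "produces": list(m.produces),
                    "direction_note": m.direction_note,
                }
                for m in self.modules
            ],
        }


def _map_from_dict(doc: dict, source: str = "<dict>") -> MetabolicMap:
    for key in ("metabolites", "modules"):
        if key not in doc:
            raise MapSchemaError(f"{source}: missing required field {key!r}")
    modules = []
    for i, rec in enumerate(doc["modules"]):
        if "name" not in rec:
            raise MapSchemaError(f"{source}: module record {i} lacks a name")
        if not rec.get("genes"):
            raise MapSchemaError(f"{source}: module {rec['name']!r} has no genes")
        modules.append(
            ReactionModule(
                name=rec["name"],
                genes=[str(g) for g in rec["genes"]],
                consumes=list(rec.get("consumes", [])),
                produces=list(rec.get("produces", [])),
                direction_note=rec.get("direction_note", ""),
            )
        )
    return MetabolicMap(
        metabolites=list(doc["metabolites"]),
        modules=modules,
        balanced_set=list(doc.get("balanced_set", [])),
        name=doc.get("name", "metabolic map"),
        description=doc.get("description", ""),
    )


def load_map(path: str | Path) -> MetabolicMap:
    """Load and validate a JSON map definition."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise MapSchemaError(f"{path}: not valid JSON ({exc})") from exc
    return _map_from_dict(doc, source=str(path))


def write_map(map_: MetabolicMap, path: str | Path) -> None:
    Path(path).write_text(json.dumps(map_.to_dict(), indent=2) + "\n")


def default_map() -> MetabolicMap:
    """The bundled cytosolic iron / ROS map (15 modules)."""
    text = resources.files("fentonflux.data").joinpath("iron_map.json").read_text()
    return _map_from_dict(json.loads(text), source="bundled iron_map.json")
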