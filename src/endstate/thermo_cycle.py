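"""Assembly of association free energies and the tetramerization cycle.

A :class:`ThermoStep` holds one association step (two monomers → dimer, or
two dimers → tetramer) as ΔH, −TΔS^conf and −TΔS^rt columns in kcal/mol
with ΔG their exact sum.  A :class:`CycleLedger` combines the two steps
into tetramerization totals, counting the monomer→dimer step twice (two
dimers form):  total = 2 × (2M→D) + (2D→T) per column.

The ΔΔG ledger tracks mutant-minus-wild-type free-energy differences along
the tetramer → dimers → monomers → unfolded-monomers pathway; the stage
values telescope to the end-to-end difference by construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from .constants import Constants, DEFAULT_CONSTANTS

__all__ = [
    "ThermoStep",
    "CycleLedger",
    "DeltaDeltaG",
    "eu_to_kcal",
    "assemble_step",
    "tetramerization_total",
    "entropic_opposition_total",
    "binding_ddg",
    "pathway_ledger",
]

_COLUMNS = ("dH", "minus_TdS_conf", "minus_TdS_rt", "dG")


@dataclass(frozen=True)
class ThermoStep:
    """One association step; all columns kcal/mol, −TΔS fields signed."""

    label: str                     # "2M->D", "2D->T", or custom
    dH: float
    minus_TdS_conf: float
    minus_TdS_rt: float
    dG: float
    T: float = 300.0
    dH_sem: float | None = None

    def column(self, name: str) -> float:
        return getattr(self, name)

    def as_dict(self) -> dict:
        d = {"label": self.label, "T": self.T}
        d.update({c: getattr(self, c) for c in _COLUMNS})
        if self.dH_sem is not None:
            d["dH_sem"] = self.dH_sem
        return d


def eu_to_kcal(dS_eu: float, T: float) -> float:
    """Convert an entropy in e.u. (cal mol⁻¹ K⁻¹) to T·ΔS in kcal/mol."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return T * dS_eu / 1000.0


def assemble_step(dH: float, minus_TdS_conf: float, minus_TdS_rt: float,
                  T: float = 300.0, label: str = "custom",
                  dH_sem: float | None = None) -> ThermoStep:
    """Build a step with ΔG = ΔH + (−TΔS^conf) + (−TΔS^rt) exactly."""
    for v in (dH, minus_TdS_conf, minus_TdS_rt):
        if not math.isfinite(v):
            raise ValueError("non-finite input")
    return ThermoStep(label=label, dH=dH, minus_TdS_conf=minus_TdS_conf,
                      minus_TdS_rt=minus_TdS_rt,
                      dG=dH + minus_TdS_conf + minus_TdS_rt, T=T, dH_sem=dH_sem)


def tetramerization_total(step_md: ThermoStep, step_dt: ThermoStep) -> dict:
    """Per-column tetramerization totals: 2 × (2M→D) + (2D→T).

    The monomer→dimer step counts twice because two dimers must form before
    they associate into the tetramer.
    """
    if step_md.T != step_dt.T:
        raise ValueError("steps must share a temperature")
    return {c: 2.0 * step_md.column(c) + step_dt.column(c) for c in _COLUMNS}


@dataclass
class CycleLedger:
    """Both association steps for one variant plus their totals."""

    variant: str                   # e.g. WT, MT, 3M
    step_md: ThermoStep            # 2M -> D
    step_dt: ThermoStep            # 2D -> T

    @property
    def totals(self) -> dict:
        return tetramerization_total(self.step_md, self.step_dt)

    def report(self) -> dict:
        """Every addend spelled out so no printed number is opaque."""
        return {
            "variant": self.variant,
            "steps": [self.step_md.as_dict(), self.step_dt.as_dict()],
            "totals": self.totals,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.report(), fh, indent=1)


def entropic_opposition_total(conf_total_kcal: float, rt_total_kcal: float) -> float:
    """Total entropic opposition to tetramerization (sum of penalties)."""
    if conf_total_kcal < 0 or rt_total_kcal < 0:
        raise ValueError("entropic penalties are reported as non-negative")
    return conf_total_kcal + rt_total_kcal


def binding_ddg(dG_complex: float, dG_parts: list[float]) -> float:
    """Interaction free energy ΔΔG = ΔG_complex − Σ ΔG_parts."""
    vals = [dG_complex, *dG_parts]
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("non-finite input")
    return dG_complex - sum(dG_parts)


@dataclass(frozen=True)
class DeltaDeltaG:
    """Mutant-minus-wild-type stage differences along T → D → M → M_unf."""

    ddG_T: float
    ddG_D: float
    ddG_M: float
    ddG_Munf: float
    source: str = ""

    @property
    def end_to_end(self) -> float:
        return self.ddG_T + self.ddG_D + self.ddG_M + self.ddG_Munf


def pathway_ledger(species_dG_mut: dict, species_dG_wt: dict,
                   source: str = "") -> DeltaDeltaG:
    """Stage-wise ΔΔG ledger of the dissociation/unfolding pathway.

    Inputs map species {"T", "D", "M", "Munf"} to free energies for mutant
    and wild type.  ΔΔG_T is the direct tetramer difference; each further
    stage is the mutant-minus-wild-type difference of that stage's ΔG step
    (ΔG_D − ΔG_T, ΔG_M − ΔG_D, ΔG_M^unf − ΔG_M).  The four stage values
    telescope exactly to the end-to-end Munf difference.
    """
    for m in (species_dG_mut, species_dG_wt):
        missing = {"T", "D", "M", "Munf"} - set(m)
        if missing:
            raise ValueError(f"missing species entries: {sorted(missing)}")
    def stage(sp_new: str, sp_old: str) -> float:
        return ((species_dG_mut[sp_new] - species_dG_mut[sp_old])
                - (species_dG_wt[sp_new] - species_dG_wt[sp_old]))
    ddg_t = species_dG_mut["T"] - species_dG_wt["T"]
    return DeltaDeltaG(
        ddG_T=ddg_t,
        ddG_D=stage("D", "T"),
        ddG_M=stage("M", "D"),
        ddG_Munf=stage("Munf", "M"),
        source=source,
    )
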