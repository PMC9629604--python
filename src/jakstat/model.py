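"""Reaction-network model of the type-I interferon JAK-STAT signaling pathway.

The network tracks 42 species in two compartments (cytoplasm, nucleus) coupled
by 62 mass-action reactions: IFN binding to the IFNAR receptor subunits,
receptor activation, STAT1/STAT2 phosphorylation, STAT heterodimerization,
ISGF3 assembly and nuclear shuttling, constitutive STAT2-IRF9 complex
formation (the driver of basal ISG expression), SOCS-mediated negative
feedback on the active receptor, and per-gene two-state promoter modules for
the four interferon-stimulated genes (ISGs) irf9, socs, mxa and ifit1 with
transcription, mRNA export, translation and first-order turnover.

Promoter semantics: each gene is a single copy resolved into three exclusive
microstates — ``I_g`` (free), ``g`` (ISGF3-bound) and ``g*``
(STAT2-IRF9-bound). Both bound states transcribe at the gene's rate; the two
transcription factors compete with identical association constants but very
different dissociation rates, so the unstimulated steady state is dominated
by STAT2-IRF9 occupancy (basal expression) and stimulation replaces it with
the much longer-lived ISGF3 occupancy.

Second-order rate constants are referenced to the whole-cell volume;
propensities of bimolecular reactions are therefore rescaled by the volume
fraction of the compartment in which they occur (1/0.135 in the nucleus,
1/0.865 in the cytoplasm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "CompartmentSpec",
    "SpeciesDef",
    "SpeciesRole",
    "Reaction",
    "ParameterSet",
    "ModelState",
    "ReactionNetwork",
    "StructuralError",
    "build_canonical_model",
    "ifn_units_to_molecules",
    "propensities",
    "ode_rhs",
    "promoter_stationary_fraction",
    "GENES",
    "IFN_MOLECULES_PER_IU",
]

#: Linear dose conversion anchored at 500 IU/mL = 10,000 molecules and
#: 250 IU/mL = 5,000 molecules.
IFN_MOLECULES_PER_IU = 20.0

#: The four ISGs, in the order their parameter quadruplets are numbered.
GENES = ("irf9", "socs", "mxa", "ifit1")

CYTOPLASM_FRACTION = 0.865
NUCLEUS_FRACTION = 0.135


class StructuralError(ValueError):
    """Raised when a network violates its structural contract."""


class SpeciesRole(str, Enum):
    LIGAND = "ligand"
    RECEPTOR = "receptor"
    PROTEIN = "protein"
    COMPLEX = "complex"
    MRNA = "mRNA"
    PROMOTER_STATE = "promoter_state"


@dataclass(frozen=True)
class CompartmentSpec:
    name: str
    volume_fraction: float

    def __post_init__(self):
        if not 0.0 < self.volume_fraction < 1.0:
            raise StructuralError(
                f"compartment {self.name}: volume fraction {self.volume_fraction} "
                "must lie in (0, 1)"
            )


@dataclass(frozen=True)
class SpeciesDef:
    name: str
    compartment: str
    role: SpeciesRole
    initial_value: float


@dataclass(frozen=True)
class Reaction:
    """A mass-action reaction; stoichiometric coefficients are positive ints."""

    id: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_parameter: str
    compartment: str = "cytoplasm"

    @property
    def order(self) -> int:
        return sum(c for _, c in self.reactants)


class ParameterSet(dict):
    """Mapping parameter name -> value (1/min or 1/(Molecules*min)).

    Units are kept in :attr:`units`; values behave as a plain dict so the
    vector can be perturbed and copied freely.
    """

    def __init__(self, values: dict[str, float], units: dict[str, str]):
        super().__init__(values)
        self.units = dict(units)
        for name, v in self.items():
            if v <= 0:
                raise StructuralError(f"parameter {name} must be > 0, got {v}")

    def copy(self) -> "ParameterSet":
        return ParameterSet(dict(self), self.units)

    def perturbed(self, name: str, factor: float) -> "ParameterSet":
        if name not in self:
            raise KeyError(f"unknown parameter {name!r}")
        out = self.copy()
        out[name] = self[name] * factor
        return out


@dataclass
class ModelState:
    time: float
    copy_numbers: np.ndarray


# --------------------------------------------------------------------------
# Rate constants.  Units: "b" = 1/(Molecules*min), "u" = 1/min.
# --------------------------------------------------------------------------

_U, _B = "1/min", "1/(Molecules*min)"

RATE_CONSTANT_TABLE: dict[str, tuple[float, str]] = {
    "k_1": (7.5e-6, _B),
    "k_2": (1.32, _B),
    "k_3": (1.75e-5, _B),
    "k_4": (1.34e-5, _B),
    "k_5": (1.0, _U),
    "k_6": (2.26, _U),
    "k_7": (9.88e-4, _B),
    "k_8": (7.59e-4, _B),
    "k_9": (8.7e-1, _U),
    "k_10": (2.63e-4, _B),
    "k_11.1": (2.2e-1, _U),
    "k_11.2": (2.5e-1, _U),
    "k_12": (1.25e-3, _B),
    "k_13.1": (2.25e-3, _U),
    "k_13.2": (2.0, _U),
    "k_14": (9.97e-4, _B),
    "k_15.1": (1.49, _U),
    "k_15.2": (107.5, _U),
    "k_16": (6.1e-4, _B),
    "k_17.1": (1.95, _U),
    "k_17.2": (22.8, _U),
    "k_18": (7.0e-4, _B),
    "k_19.1": (8.71e-1, _U),
    "k_19.2": (10.6, _U),
    "k_20": (3.28e-1, _U),
    "k_21": (1.47e-1, _U),
    "k_22": (1.34e-2, _U),
    "k_23": (1.4e-2, _U),
    "k_24": (8.76e-1, _U),
    "k_25": (4.89, _U),
    "k_26": (1.38, _U),
    "k_27": (1.04e-1, _U),
    "k_28": (1.39e-2, _U),
    "k_29": (4.36e-2, _U),
    "k_30": (2.38e-3, _U),
    "k_31": (7.37e-3, _U),
    "k_32": (8.64e-1, _U),
    "k_33": (6.26e-1, _U),
    "k_34": (1.52, _U),
    "k_35": (4.02, _U),
    "k_36": (1.73e-1, _U),
    "k_37": (2.5e-2, _U),
    "k_38": (3.51e-4, _U),
    "k_39": (1.95e-3, _U),
    "k_40": (1.85e-2, _U),
    "k_41": (1.18e-2, _U),
    "k_42": (5.09e-3, _U),
    "k_43": (1.43e-2, _U),
    "k_44": (5.05e-4, _B),
    "k_45": (2.94e-3, _U),
    "k_46": (1.2e-3, _U),
    "k_47": (4.77e-2, _U),
}

# --------------------------------------------------------------------------
# Species, compartments, roles, initial conditions (copies/cell; promoter
# microstates carry occupancy probabilities of the single gene copy).
# --------------------------------------------------------------------------

_C, _N = "cytoplasm", "nucleus"
_R = SpeciesRole

SPECIES_TABLE: list[tuple[str, str, SpeciesRole, float]] = [
    ("IFN", _C, _R.LIGAND, 0.0),  # set per dose; 250 IU/mL -> 5000
    ("R2", _C, _R.RECEPTOR, 1000.0),
    ("RC", _C, _R.RECEPTOR, 0.0),
    ("R1", _C, _R.RECEPTOR, 1000.0),
    ("AR", _C, _R.RECEPTOR, 0.0),
    ("STAT1_c", _C, _R.PROTEIN, 850667.0),
    ("STAT1_n", _N, _R.PROTEIN, 0.0),
    ("STAT2_c", _C, _R.PROTEIN, 9325.0),
    ("STAT2_n", _N, _R.PROTEIN, 150.0),
    ("SOCS", _C, _R.PROTEIN, 0.0),
    ("dimerSTAT", _C, _R.COMPLEX, 0.0),
    ("IRF9_c", _C, _R.PROTEIN, 10.0),
    ("IRF9_n", _N, _R.PROTEIN, 60.0),
    ("ISGF3_c", _C, _R.COMPLEX, 0.0),
    ("ISGF3_n", _N, _R.COMPLEX, 0.0),
    ("STAT2-IRF9_c", _C, _R.COMPLEX, 200.0),
    ("STAT2-IRF9_n", _N, _R.COMPLEX, 325.0),
    ("pSTAT1", _C, _R.PROTEIN, 0.0),
    ("pSTAT2", _C, _R.PROTEIN, 0.0),
    ("IR", _C, _R.RECEPTOR, 0.0),
    ("mIRF9_c", _C, _R.MRNA, 14.0),
    ("mIRF9_n", _N, _R.MRNA, 0.0),
    ("mSOCS_c", _C, _R.MRNA, 0.0),  # long-run basal average ~0.08
    ("mSOCS_n", _N, _R.MRNA, 0.0),
    ("mMxA_c", _C, _R.MRNA, 0.0),  # long-run basal average ~0.2
    ("mMxA_n", _N, _R.MRNA, 0.0),
    ("mIFIT1_c", _C, _R.MRNA, 0.0),  # long-run basal average ~0.2
    ("mIFIT1_n", _N, _R.MRNA, 0.0),
    ("MxA", _C, _R.PROTEIN, 1582.0),
    ("IFIT1", _C, _R.PROTEIN, 705.0),
    ("irf9", _N, _R.PROMOTER_STATE, 0.0),
    ("socs", _N, _R.PROMOTER_STATE, 0.0),
    ("ifit1", _N, _R.PROMOTER_STATE, 0.0),
    ("mxa", _N, _R.PROMOTER_STATE, 0.0),
    ("irf9*", _N, _R.PROMOTER_STATE, 0.62),
    ("socs*", _N, _R.PROMOTER_STATE, 0.02),
    ("mxa*", _N, _R.PROMOTER_STATE, 0.06),
    ("ifit1*", _N, _R.PROMOTER_STATE, 0.11),
    ("I_irf9", _N, _R.PROMOTER_STATE, 0.38),
    ("I_socs", _N, _R.PROMOTER_STATE, 0.98),
    ("I_mxa", _N, _R.PROMOTER_STATE, 0.94),
    ("I_ifit1", _N, _R.PROMOTER_STATE, 0.89),
]

COMPARTMENT_TABLE = (
    CompartmentSpec("cytoplasm", CYTOPLASM_FRACTION),
    CompartmentSpec("nucleus", NUCLEUS_FRACTION),
)

# --------------------------------------------------------------------------
# Reaction table m1..m62.
#
# The k-index -> reaction assignment below is the package's reconstruction of
# the pathway wiring (an editable table, deliberately kept as data).  The
# promoter association constant of each gene serves both transcription
# factors; the .1/.2 splits are the ISGF3 / STAT2-IRF9 dissociation rates.
# --------------------------------------------------------------------------


def _rxn(rid, reactants, products, k, comp=_C) -> Reaction:
    return Reaction(rid, tuple(reactants), tuple(products), k, comp)


def _canonical_reactions() -> list[Reaction]:
    rx: list[Reaction] = []
    add = rx.append

    # --- receptor module ---------------------------------------------------
    add(_rxn("m1", [("IFN", 1), ("R1", 1)], [("IR", 1)], "k_1"))
    add(_rxn("m2", [("IR", 1)], [("IFN", 1), ("R1", 1)], "k_5"))
    add(_rxn("m3", [("IR", 1), ("R2", 1)], [("RC", 1)], "k_3"))
    add(_rxn("m4", [("RC", 1)], [("AR", 1)], "k_6"))
    # SOCS negative feedback: degradation of the active complex.  The bound
    # IFN is destroyed; the receptor subunits re-enter the inactive pool
    # (the model carries no receptor synthesis, so signaling capacity is
    # conserved while the ligand is consumed).
    add(_rxn("m5", [("AR", 1), ("SOCS", 1)], [("R1", 1), ("R2", 1), ("SOCS", 1)], "k_44"))
    # slow constitutive decay of the active complex, same products
    add(_rxn("m6", [("AR", 1)], [("R1", 1), ("R2", 1)], "k_46"))

    # --- STAT phosphorylation (catalyzed by the active receptor) -----------
    add(_rxn("m7", [("AR", 1), ("STAT1_c", 1)], [("AR", 1), ("pSTAT1", 1)], "k_7"))
    add(_rxn("m8", [("AR", 1), ("STAT2_c", 1)], [("AR", 1), ("pSTAT2", 1)], "k_8"))
    add(_rxn("m9", [("pSTAT1", 1)], [("STAT1_c", 1)], "k_42"))

    # --- heterodimer and ISGF3 assembly ------------------------------------
    add(_rxn("m10", [("pSTAT1", 1), ("pSTAT2", 1)], [("dimerSTAT", 1)], "k_2"))
    add(_rxn("m11", [("pSTAT2", 1)], [("STAT2_c", 1)], "k_9"))
    add(_rxn("m12", [("dimerSTAT", 1), ("IRF9_c", 1)], [("ISGF3_c", 1)], "k_10"))
    add(_rxn("m13", [("ISGF3_c", 1)], [("ISGF3_n", 1)], "k_11.1"))
    add(_rxn("m14", [("ISGF3_n", 1)], [("ISGF3_c", 1)], "k_11.2"))
    # nuclear disassembly of ISGF3 (dephosphorylation), releasing components
    add(
        _rxn(
            "m15",
            [("ISGF3_n", 1)],
            [("STAT1_n", 1), ("STAT2_n", 1), ("IRF9_n", 1)],
            "k_41",
            _N,
        )
    )
    add(_rxn("m16", [("IRF9_n", 1)], [("IRF9_c", 1)], "k_43", _N))

    # --- constitutive STAT2-IRF9 (basal expression driver) -----------------
    add(_rxn("m17", [("STAT2_c", 1), ("IRF9_c", 1)], [("STAT2-IRF9_c", 1)], "k_4"))
    add(_rxn("m18", [("STAT2-IRF9_c", 1)], [("STAT2-IRF9_n", 1)], "k_47"))
    add(_rxn("m19", [("STAT2-IRF9_n", 1)], [("STAT2-IRF9_c", 1)], "k_43", _N))
    # complex turnover degrades IRF9 and recycles STAT2
    add(_rxn("m20", [("STAT2-IRF9_c", 1)], [("STAT2_c", 1)], "k_37"))
    add(_rxn("m21", [("STAT2-IRF9_n", 1)], [("STAT2_n", 1)], "k_37", _N))

    # --- STAT2 nucleocytoplasmic shuttling ----------------------------------
    add(_rxn("m22", [("STAT2_c", 1)], [("STAT2_n", 1)], "k_45"))
    add(_rxn("m23", [("STAT2_n", 1)], [("STAT2_c", 1)], "k_36", _N))

    # --- two-state promoter modules (competitive TF binding) ---------------
    assoc = {"irf9": "k_12", "socs": "k_14", "mxa": "k_16", "ifit1": "k_18"}
    diss_isgf3 = {"irf9": "k_13.1", "socs": "k_15.1", "mxa": "k_17.1", "ifit1": "k_19.1"}
    diss_s2irf9 = {"irf9": "k_13.2", "socs": "k_15.2", "mxa": "k_17.2", "ifit1": "k_19.2"}
    m = 24
    for g in GENES:
        add(_rxn(f"m{m}", [(f"I_{g}", 1), ("ISGF3_n", 1)], [(g, 1)], assoc[g], _N))
        add(_rxn(f"m{m+1}", [(g, 1)], [(f"I_{g}", 1), ("ISGF3_n", 1)], diss_isgf3[g], _N))
        add(
            _rxn(
                f"m{m+2}",
                [(f"I_{g}", 1), ("STAT2-IRF9_n", 1)],
                [(f"{g}*", 1)],
                assoc[g],
                _N,
            )
        )
        add(
            _rxn(
                f"m{m+3}",
                [(f"{g}*", 1)],
                [(f"I_{g}", 1), ("STAT2-IRF9_n", 1)],
                diss_s2irf9[g],
                _N,
            )
        )
        m += 4

    # --- transcription from either bound promoter state --------------------
    tx = {"irf9": "k_20", "socs": "k_21", "mxa": "k_22", "ifit1": "k_23"}
    nuc_mrna = {"irf9": "mIRF9_n", "socs": "mSOCS_n", "mxa": "mMxA_n", "ifit1": "mIFIT1_n"}
    for g in GENES:
        add(_rxn(f"m{m}", [(g, 1)], [(g, 1), (nuc_mrna[g], 1)], tx[g], _N))
        add(_rxn(f"m{m+1}", [(f"{g}*", 1)], [(f"{g}*", 1), (nuc_mrna[g], 1)], tx[g], _N))
        m += 2

    # --- mRNA export, degradation, translation ------------------------------
    cyt_mrna = {"irf9": "mIRF9_c", "socs": "mSOCS_c", "mxa": "mMxA_c", "ifit1": "mIFIT1_c"}
    exp = {"irf9": "k_24", "socs": "k_27", "mxa": "k_26", "ifit1": "k_25"}
    deg = {"irf9": "k_28", "socs": "k_29", "mxa": "k_30", "ifit1": "k_31"}
    tl = {"irf9": "k_32", "socs": "k_33", "mxa": "k_34", "ifit1": "k_35"}
    protein = {"irf9": "IRF9_c", "socs": "SOCS", "mxa": "MxA", "ifit1": "IFIT1"}
    for g in GENES:
        add(_rxn(f"m{m}", [(nuc_mrna[g], 1)], [(cyt_mrna[g], 1)], exp[g], _N))
        m += 1
    for g in GENES:
        add(_rxn(f"m{m}", [(cyt_mrna[g], 1)], [], deg[g]))
        m += 1
    for g in GENES:
        add(_rxn(f"m{m}", [(cyt_mrna[g], 1)], [(cyt_mrna[g], 1), (protein[g], 1)], tl[g]))
        m += 1

    # --- ISG / feedback protein turnover ------------------------------------
    add(_rxn(f"m{m}", [("SOCS", 1)], [], "k_40")); m += 1
    add(_rxn(f"m{m}", [("MxA", 1)], [], "k_38")); m += 1
    add(_rxn(f"m{m}", [("IFIT1", 1)], [], "k_39")); m += 1

    return rx


# --------------------------------------------------------------------------
# ReactionNetwork
# --------------------------------------------------------------------------


@dataclass
class CompiledNetwork:
    """Flat array form of the network consumed by the simulation kernels."""

    stoich: np.ndarray        # (n_reactions, n_species) int64 net change
    reactant1: np.ndarray     # (n_reactions,) int64 species index
    reactant2: np.ndarray     # (n_reactions,) int64 species index or -1
    rates: np.ndarray         # (n_reactions,) float64 volume-corrected constants
    consumed: np.ndarray      # (n_reactions, n_species) int64 reactant coefficients


@dataclass
class ReactionNetwork:
    species: list[SpeciesDef]
    compartments: tuple[CompartmentSpec, ...]
    reactions: list[Reaction]
    parameters: ParameterSet

    def __post_init__(self):
        self._index = {s.name: i for i, s in enumerate(self.species)}
        self.validate()

    # -- lookups -------------------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self, name: str) -> int:
        return self._index[name]

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_value for s in self.species], dtype=float)

    def promoter_triples(self) -> dict[str, tuple[int, int, int]]:
        """Per gene, indices of (free, ISGF3-bound, STAT2-IRF9-bound) states.

        Genes absent from the species table (e.g. in reduced test networks)
        are skipped.
        """
        return {
            g: (self._index[f"I_{g}"], self._index[g], self._index[f"{g}*"])
            for g in GENES
            if f"I_{g}" in self._index
        }

    def with_initial_values(self, overrides) -> "ReactionNetwork":
        """New network with replaced initial values.

        ``overrides`` is either a mapping species name -> value or a full
        vector in species order.
        """
        if not isinstance(overrides, dict):
            vec = np.asarray(overrides, dtype=float)
            overrides = {s.name: vec[i] for i, s in enumerate(self.species)}
        species = [
            SpeciesDef(
                s.name,
                s.compartment,
                s.role,
                float(overrides.get(s.name, s.initial_value)),
            )
            for s in self.species
        ]
        return ReactionNetwork(species, self.compartments, self.reactions, self.parameters)

    def molecular_species(self) -> list[str]:
        """Species that are molecule counts (everything but promoter states)."""
        return [
            s.name for s in self.species if s.role is not SpeciesRole.PROMOTER_STATE
        ]

    # -- validation ----------------------------------------------------------
    def validate(self) -> None:
        problems: list[str] = []
        if abs(sum(c.volume_fraction for c in self.compartments) - 1.0) > 1e-9:
            problems.append("compartment volume fractions do not sum to 1")
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            problems.append("duplicate species names")
        for rxn in self.reactions:
            if rxn.rate_parameter not in self.parameters:
                problems.append(f"{rxn.id}: unknown parameter {rxn.rate_parameter}")
            for sp, _ in rxn.reactants + rxn.products:
                if sp not in self._index:
                    problems.append(f"{rxn.id}: unknown species {sp}")
        used = set()
        for rxn in self.reactions:
            for sp, _ in rxn.reactants + rxn.products:
                used.add(sp)
        unused = set(names) - used
        if unused:
            problems.append(f"species in no reaction: {sorted(unused)}")
        # per-gene promoter conservation, both stoichiometric and initial
        for g, (i_free, i_a, i_b) in self.promoter_triples().items():
            total0 = sum(self.species[i].initial_value for i in (i_free, i_a, i_b))
            if abs(total0 - 1.0) > 1e-9:
                problems.append(f"gene {g}: initial promoter states sum to {total0}")
            S = self.stoichiometry_matrix()
            net = S[:, [i_free, i_a, i_b]].sum(axis=1)
            if np.any(net != 0):
                bad = [self.reactions[j].id for j in np.nonzero(net)[0]]
                problems.append(f"gene {g}: promoter total not conserved by {bad}")
        if problems:
            raise StructuralError("structural report:\n- " + "\n- ".join(problems))

    def check_canonical_counts(self) -> None:
        problems = []
        if self.n_species != 42:
            problems.append(f"expected 42 species, found {self.n_species}")
        if self.n_reactions != 62:
            problems.append(f"expected 62 reactions, found {self.n_reactions}")
        referenced = {r.rate_parameter for r in self.reactions}
        missing = set(self.parameters) - referenced
        if missing:
            problems.append(f"parameters referenced by no reaction: {sorted(missing)}")
        if problems:
            raise StructuralError("structural report:\n- " + "\n- ".join(problems))

    # -- matrices ------------------------------------------------------------
    def stoichiometry_matrix(self) -> np.ndarray:
        S = np.zeros((self.n_reactions, self.n_species), dtype=np.int64)
        for j, rxn in enumerate(self.reactions):
            for sp, c in rxn.reactants:
                S[j, self._index[sp]] -= c
            for sp, c in rxn.products:
                S[j, self._index[sp]] += c
        return S

    def volume_fraction(self, compartment: str) -> float:
        for c in self.compartments:
            if c.name == compartment:
                return c.volume_fraction
        raise KeyError(compartment)

    def rate_vector(self, params: ParameterSet | None = None) -> np.ndarray:
        """Effective rate constants: bimolecular constants are divided by the
        volume fraction of the reaction's compartment."""
        p = self.parameters if params is None else params
        rates = np.empty(self.n_reactions)
        for j, rxn in enumerate(self.reactions):
            k = p[rxn.rate_parameter]
            if rxn.order == 2:
                k = k / self.volume_fraction(rxn.compartment)
            rates[j] = k
        return rates

    def compiled(self, params: ParameterSet | None = None) -> CompiledNetwork:
        r1 = np.full(self.n_reactions, -1, dtype=np.int64)
        r2 = np.full(self.n_reactions, -1, dtype=np.int64)
        # net consumption per reaction (catalysts cannot go negative and so
        # do not make a reaction critical in the tau-leap engine)
        consumed = np.zeros((self.n_reactions, self.n_species), dtype=np.int64)
        for j, rxn in enumerate(self.reactions):
            flat = []
            prod = {sp: c for sp, c in rxn.products}
            for sp, c in rxn.reactants:
                consumed[j, self._index[sp]] = max(c - prod.get(sp, 0), 0)
                flat.extend([self._index[sp]] * c)
            if len(flat) > 2:
                raise StructuralError(f"{rxn.id}: order > 2 not supported")
            if len(flat) == 2 and flat[0] == flat[1]:
                raise StructuralError(
                    f"{rxn.id}: identical-reactant bimolecular reactions "
                    "are not supported"
                )
            if len(flat) >= 1:
                r1[j] = flat[0]
            if len(flat) == 2:
                r2[j] = flat[1]
        return CompiledNetwork(
            stoich=self.stoichiometry_matrix(),
            reactant1=r1,
            reactant2=r2,
            rates=self.rate_vector(params),
            consumed=consumed,
        )

    # -- serialization -------------------------------------------------------
    def to_text(self) -> str:
        lines = ["# jakstat model v1", "[compartments]"]
        for c in self.compartments:
            lines.append(f"{c.name} = {float(c.volume_fraction)!r}")
        lines.append("[species]")
        for s in self.species:
            lines.append(
                f"{s.name} | {s.compartment} | {s.role.value} | {float(s.initial_value)!r}"
            )
        lines.append("[parameters]")
        for name, v in self.parameters.items():
            lines.append(f"{name} = {float(v)!r} | {self.parameters.units[name]}")
        lines.append("[reactions]")
        for r in self.reactions:
            lhs = " + ".join(f"{c} {sp}" for sp, c in r.reactants) or "0"
            rhs = " + ".join(f"{c} {sp}" for sp, c in r.products) or "0"
            lines.append(f"{r.id}: {lhs} -> {rhs} @ {r.rate_parameter} in {r.compartment}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ReactionNetwork":
        section = None
        comps: list[CompartmentSpec] = []
        species: list[SpeciesDef] = []
        values: dict[str, float] = {}
        units: dict[str, str] = {}
        reactions: list[Reaction] = []
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                section = line[1:-1]
                continue
            if section == "compartments":
                name, v = (x.strip() for x in line.split("="))
                comps.append(CompartmentSpec(name, float(v)))
            elif section == "species":
                name, comp, role, v = (x.strip() for x in line.split("|"))
                species.append(SpeciesDef(name, comp, SpeciesRole(role), float(v)))
            elif section == "parameters":
                lhs, unit = (x.strip() for x in line.rsplit("|", 1))
                name, v = (x.strip() for x in lhs.split("="))
                values[name] = float(v)
                units[name] = unit
            elif section == "reactions":
                rid, rest = (x.strip() for x in line.split(":", 1))
                eqn, comp = (x.strip() for x in rest.rsplit(" in ", 1))
                lhs_rhs, param = (x.strip() for x in eqn.rsplit("@", 1))
                lhs, rhs = (x.strip() for x in lhs_rhs.split("->"))

                def _side(s: str) -> tuple[tuple[str, int], ...]:
                    if s == "0":
                        return ()
                    out = []
                    for term in s.split(" + "):
                        c, sp = term.split(" ", 1)
                        out.append((sp.strip(), int(c)))
                    return tuple(out)

                reactions.append(Reaction(rid, _side(lhs), _side(rhs), param, comp))
        return cls(species, tuple(comps), reactions, ParameterSet(values, units))


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------


def build_canonical_model(ifn_molecules: float = 0.0) -> ReactionNetwork:
    """Assemble the canonical 42-species / 62-reaction network.

    Parameters
    ----------
    ifn_molecules:
        Initial extracellular IFN copy number (use
        :func:`ifn_units_to_molecules` to convert a dose in IU/mL).
    """
    if ifn_molecules < 0:
        raise ValueError("IFN molecule count must be non-negative")
    species = [
        SpeciesDef(n, c, r, ifn_molecules if n == "IFN" else v)
        for (n, c, r, v) in SPECIES_TABLE
    ]
    params = ParameterSet(
        {k: v for k, (v, u) in RATE_CONSTANT_TABLE.items()},
        {k: u for k, (v, u) in RATE_CONSTANT_TABLE.items()},
    )
    net = ReactionNetwork(species, COMPARTMENT_TABLE, _canonical_reactions(), params)
    net.check_canonical_counts()
    return net


def ifn_units_to_molecules(dose_iu_per_ml: float) -> int:
    """Convert an IFN dose (IU/mL) to an initial molecule count.

    Linear map at 20 molecules per IU/mL (500 IU/mL = 10,000 molecules),
    rounded to the nearest integer.
    """
    if dose_iu_per_ml < 0:
        raise ValueError("dose must be non-negative")
    return int(round(dose_iu_per_ml * IFN_MOLECULES_PER_IU))


def propensities(
    state: ModelState | np.ndarray,
    params: ParameterSet,
    network: ReactionNetwork,
) -> np.ndarray:
    """Mass-action propensities (1/min) for every reaction at a state."""
    x = state.copy_numbers if isinstance(state, ModelState) else np.asarray(state)
    c = network.compiled(params)
    return _propensities_from_compiled(x, c)


def _propensities_from_compiled(x: np.ndarray, c: CompiledNetwork) -> np.ndarray:
    a = c.rates.copy()
    has1 = c.reactant1 >= 0
    a[has1] *= x[c.reactant1[has1]]
    has2 = c.reactant2 >= 0
    a[has2] *= x[c.reactant2[has2]]
    return np.maximum(a, 0.0)


def ode_rhs(
    t: float,
    x: np.ndarray,
    network: ReactionNetwork,
    params: ParameterSet | None = None,
) -> np.ndarray:
    """First-moment (mean-field) right-hand side dX/dt = S^T a(X)."""
    c = network.compiled(params)
    a = _propensities_from_compiled(np.maximum(x, 0.0), c)
    return c.stoich.T @ a


def promoter_stationary_fraction(k_on: float, tf_count: float, k_off: float) -> float:
    """Stationary bound fraction of a two-state promoter facing a single
    transcription factor held at fixed abundance ``tf_count``."""
    if k_on <= 0 or k_off <= 0:
        raise ValueError("k_on and k_off must be positive")
    if tf_count < 0:
        raise ValueError("tf_count must be non-negative")
    a = k_on * tf_count
    return a / (a + k_off)
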