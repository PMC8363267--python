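"""Reaction-network container: species, mass-action reactions, knockouts.

The model is a single well-mixed compartment.  Species are declared with a
total (initial) concentration in nM; reactions are elementary mass-action
steps of stoichiometric order at most two per side, with a forward rate
constant ``kf`` (per-nM per-s for bimolecular steps, per-s for unimolecular,
nM per-s for zeroth-order sources) and an optional reverse rate ``kr``.

Networks are plain data.  They are loaded from tabular text (one TSV/CSV per
reaction group plus a species table), serialised back bit-exactly, and
transformed functionally: :func:`apply_knockout` always returns a copy.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import sympy

ROLE_TAGS = frozenset(
    {"input", "kinase", "phosphatase", "gtpase", "gef", "gap", "buffer", "pump", "other"}
)


class NetworkSchemaError(ValueError):
    """A parameter table references an unknown species or is malformed."""


class NetworkValidationError(ValueError):
    """A structurally parsed network violates an invariant (e.g. negative rate)."""


@dataclass(frozen=True)
class SpeciesSpec:
    """One molecular species: a name, its initial concentration and a role tag."""

    name: str
    initial_concentration: float  # nM
    role_tag: str = "other"

    def __post_init__(self) -> None:
        if self.initial_concentration < 0:
            raise NetworkValidationError(
                f"species {self.name!r}: initial concentration must be >= 0, "
                f"got {self.initial_concentration}"
            )
        if self.role_tag not in ROLE_TAGS:
            raise NetworkValidationError(
                f"species {self.name!r}: unknown role_tag {self.role_tag!r}; "
                f"valid tags: {sorted(ROLE_TAGS)}"
            )


@dataclass(frozen=True)
class ReactionSpec:
    """One elementary reaction.

    ``reactants`` and ``products`` are tuples of species names; a species
    appearing twice has stoichiometry two.  An empty reactant tuple denotes a
    zeroth-order source; an empty product tuple a degradation sink.
    """

    label: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    kf: float
    kr: float | None = None

    def __post_init__(self) -> None:
        for side, names in (("reactant", self.reactants), ("product", self.products)):
            if len(names) > 2:
                raise NetworkValidationError(
                    f"reaction {self.label!r}: {side} stoichiometric order "
                    f"{len(names)} exceeds 2"
                )
        if self.kf < 0:
            raise NetworkValidationError(
                f"reaction {self.label!r}: negative forward rate {self.kf}"
            )
        if self.kr is not None and self.kr < 0:
            raise NetworkValidationError(
                f"reaction {self.label!r}: negative reverse rate {self.kr}"
            )
        if self.kr is not None and not self.products:
            raise NetworkValidationError(
                f"reaction {self.label!r}: reversible reaction needs products"
            )

    @property
    def reversible(self) -> bool:
        return self.kr is not None


@dataclass(frozen=True)
class ReactionNetwork:
    """A validated set of species and reactions in one compartment.

    ``metadata`` carries free-form tags; the built-in fixture sets
    ``metadata["fixture"] = True`` so downstream suites can refuse
    paper-value comparisons on it.  ``metadata`` may also name reaction
    labels implementing Raf dimerization ("dimerization_labels") and SynGap
    dispersion ("dispersion_labels") so the corresponding knockout flags
    know what to zero.
    """

    species: tuple[SpeciesSpec, ...]
    reactions: tuple[ReactionSpec, ...]
    compartment_volume: float = 4.0  # µm³
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise NetworkValidationError(f"duplicate species names: {dupes}")
        if self.compartment_volume <= 0:
            raise NetworkValidationError(
                f"compartment volume must be > 0 µm³, got {self.compartment_volume}"
            )
        declared = set(names)
        for rx in self.reactions:
            for nm in (*rx.reactants, *rx.products):
                if nm not in declared:
                    raise NetworkSchemaError(
                        f"reaction {rx.label!r} references undeclared species {nm!r}"
                    )

    # -- lookups ---------------------------------------------------------

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def initial_concentrations(self) -> np.ndarray:
        """Initial concentrations in nM, ordered as ``species``."""
        return np.array([s.initial_concentration for s in self.species], float)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r.label for r in self.reactions)

    def is_fixture(self) -> bool:
        return bool(self.metadata.get("fixture", False))

    # -- stoichiometry ---------------------------------------------------

    def stoichiometry(self) -> tuple[np.ndarray, np.ndarray]:
        """(reactant_orders, net_change), each shaped (n_species, n_directed).

        Reversible reactions contribute two directed columns (forward then
        reverse); irreversible ones a single column.
        """
        cols_sub: list[np.ndarray] = []
        cols_net: list[np.ndarray] = []
        idx = {n: i for i, n in enumerate(self.species_names)}
        for rx in self.reactions:
            sub = np.zeros(len(self.species))
            prod = np.zeros(len(self.species))
            for nm in rx.reactants:
                sub[idx[nm]] += 1
            for nm in rx.products:
                prod[idx[nm]] += 1
            cols_sub.append(sub)
            cols_net.append(prod - sub)
            if rx.reversible:
                cols_sub.append(prod)
                cols_net.append(sub - prod)
        if not cols_sub:
            return np.zeros((len(self.species), 0)), np.zeros((len(self.species), 0))
        return np.stack(cols_sub, axis=1), np.stack(cols_net, axis=1)

    def conserved_moieties(self) -> list[dict[str, int]]:
        """Integer left-null-space vectors of the net stoichiometry matrix.

        Each returned mapping {species: coefficient} defines a total that is
        invariant along any trajectory of the network.  Computed exactly with
        rational arithmetic, then scaled to coprime integers.
        """
        _, net = self.stoichiometry()
        mat = sympy.Matrix(net.astype(int)).T  # rows: directed reactions
        basis = mat.nullspace()
        out: list[dict[str, int]] = []
        for vec in basis:
            denom = sympy.lcm([sympy.fraction(x)[1] for x in vec])
            ints = [int(x * denom) for x in vec]
            g = math.gcd(*ints) if any(ints) else 1
            ints = [x // (g or 1) for x in ints]
            if sum(x for x in ints if x != 0) < 0:
                ints = [-x for x in ints]
            out.append(
                {n: c for n, c in zip(self.species_names, ints) if c != 0}
            )
        return out

    # -- transforms ------------------------------------------------------

    def with_species_concentration(self, name: str, conc: float) -> "ReactionNetwork":
        i = self.species_index(name)
        new = list(self.species)
        new[i] = replace(new[i], initial_concentration=conc)
        return replace(self, species=tuple(new))

    # -- serialisation ---------------------------------------------------

    def to_tables(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(species table, reaction table) in the native tabular schema."""
        sp = pd.DataFrame(
            {
                "name": [s.name for s in self.species],
                "concentration_nM": [
                    _format_number(s.initial_concentration) for s in self.species
                ],
                "role": [s.role_tag for s in self.species],
            }
        )
        rx = pd.DataFrame(
            {
                "label": [r.label for r in self.reactions],
                "reactants": [" + ".join(r.reactants) for r in self.reactions],
                "products": [" + ".join(r.products) for r in self.reactions],
                "kf": [_format_number(r.kf) for r in self.reactions],
                "kr": ["" if r.kr is None else _format_number(r.kr) for r in self.reactions],
            }
        )
        return sp, rx

    def write_tables(self, species_path: str | Path, reactions_path: str | Path) -> None:
        sp, rx = self.to_tables()
        sp.to_csv(species_path, sep="\t", index=False)
        rx.to_csv(reactions_path, sep="\t", index=False)


def _format_number(x: float) -> str:
    """Shortest repr that round-trips; keeps table serialisation bit-stable."""
    return repr(float(x))


# ---------------------------------------------------------------------------
# loading


def _parse_side(text: object, row_label: str) -> tuple[str, ...]:
    if text is None or (isinstance(text, float) and math.isnan(text)):
        return ()
    s = str(text).strip()
    if not s:
        return ()
    names = tuple(part.strip() for part in s.split("+"))
    if any(not n for n in names):
        raise NetworkSchemaError(f"reaction {row_label!r}: malformed side {text!r}")
    return names


def _read_table(table: str | Path | pd.DataFrame) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    path = Path(table)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def load_network(
    species_table: str | Path | pd.DataFrame,
    reaction_tables: Sequence[str | Path | pd.DataFrame],
    volume: float = 4.0,
    metadata: Mapping[str, object] | None = None,
) -> ReactionNetwork:
    """Build a validated :class:`ReactionNetwork` from tabular text.

    ``species_table`` needs columns ``name``, ``concentration_nM`` and
    optionally ``role``; each reaction table needs ``label``, ``reactants``,
    ``products``, ``kf`` and optionally ``kr``.  Several reaction tables may
    be passed (the published model splits its reactions across source-data
    files); the resulting network has exactly as many reactions as the
    tables have rows.
    """
    sp_df = _read_table(species_table)
    for col in ("name", "concentration_nM"):
        if col not in sp_df.columns:
            raise NetworkSchemaError(f"species table lacks required column {col!r}")
    species = []
    for _, row in sp_df.iterrows():
        try:
            conc = float(row["concentration_nM"])
        except ValueError:
            raise NetworkSchemaError(
                f"species {row['name']!r}: non-numeric concentration "
                f"{row['concentration_nM']!r}"
            ) from None
        role = str(row.get("role", "other") or "other")
        species.append(SpeciesSpec(str(row["name"]), conc, role))

    reactions: list[ReactionSpec] = []
    for tab in reaction_tables:
        rx_df = _read_table(tab)
        for col in ("label", "reactants", "products", "kf"):
            if col not in rx_df.columns:
                raise NetworkSchemaError(f"reaction table lacks required column {col!r}")
        for _, row in rx_df.iterrows():
            label = str(row["label"])
            kr_raw = str(row.get("kr", "") or "").strip()
            try:
                kf = float(row["kf"])
                kr = float(kr_raw) if kr_raw else None
            except ValueError:
                raise NetworkSchemaError(
                    f"reaction {label!r}: non-numeric rate constant"
                ) from None
            reactions.append(
                ReactionSpec(
                    label=label,
                    reactants=_parse_side(row["reactants"], label),
                    products=_parse_side(row["products"], label),
                    kf=kf,
                    kr=kr,
                )
            )
    return ReactionNetwork(
        species=tuple(species),
        reactions=tuple(reactions),
        compartment_volume=volume,
        metadata=dict(metadata or {}),
    )


# ---------------------------------------------------------------------------
# knockouts


@dataclass(frozen=True)
class KnockoutConfig:
    """A block/overexpression experiment applied to a network.

    ``zeroed_rate_labels`` sets kf = kr = 0 for every reaction carrying the
    label (the published experiments zero labels such as K_CK, K_Syn1,
    K_Epac); ``removed_species`` zeroes initial amounts (Ras / Rap1 / Raf
    knockouts); ``quantity_multipliers`` rescales initial amounts
    (e.g. doubling Rap1).  ``dimerization_enabled`` / ``dispersion_enabled``
    zero the label sets the network's metadata declares for Raf
    dimerization and SynGap dispersion.
    """

    zeroed_rate_labels: frozenset[str] = frozenset()
    removed_species: frozenset[str] = frozenset()
    quantity_multipliers: Mapping[str, float] = field(default_factory=dict)
    dimerization_enabled: bool = True
    dispersion_enabled: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "zeroed_rate_labels", frozenset(self.zeroed_rate_labels))
        object.__setattr__(self, "removed_species", frozenset(self.removed_species))
        object.__setattr__(self, "quantity_multipliers", dict(self.quantity_multipliers))
        for sp, f in self.quantity_multipliers.items():
            if f <= 0:
                raise NetworkValidationError(
                    f"quantity multiplier for {sp!r} must be > 0, got {f}"
                )


def apply_knockout(net: ReactionNetwork, ko: KnockoutConfig) -> ReactionNetwork:
    """Return a copy of ``net`` with the knockout applied; ``net`` is untouched."""
    valid_labels = set(net.labels)
    to_zero = set(ko.zeroed_rate_labels)
    if not ko.dimerization_enabled:
        to_zero |= set(net.metadata.get("dimerization_labels", ()))
    if not ko.dispersion_enabled:
        to_zero |= set(net.metadata.get("dispersion_labels", ()))
    unknown = to_zero - valid_labels
    if unknown:
        raise KeyError(
            f"unknown reaction labels {sorted(unknown)}; valid labels: "
            f"{sorted(valid_labels)}"
        )
    declared = set(net.species_names)
    bad_species = (set(ko.removed_species) | set(ko.quantity_multipliers)) - declared
    if bad_species:
        raise KeyError(f"unknown species {sorted(bad_species)} in knockout config")

    new_reactions = tuple(
        replace(rx, kf=0.0, kr=(0.0 if rx.kr is not None else None))
        if rx.label in to_zero
        else rx
        for rx in net.reactions
    )
    new_species = []
    for sp in net.species:
        conc = sp.initial_concentration
        if sp.name in ko.removed_species:
            conc = 0.0
        elif sp.name in ko.quantity_multipliers:
            conc = conc * ko.quantity_multipliers[sp.name]
        new_species.append(replace(sp, initial_concentration=conc))
    return replace(net, species=tuple(new_species), reactions=new_reactions)


# ---------------------------------------------------------------------------
# validation report


@dataclass(frozen=True)
class ValidationReport:
    conserved_moieties: tuple[dict[str, int], ...]
    dangling_species: tuple[str, ...]
    zero_rate_reactions: tuple[str, ...]
    violated_moieties: tuple[frozenset[str], ...] = ()

    @property
    def ok(self) -> bool:
        return not self.violated_moieties


def moiety_is_conserved(net: ReactionNetwork, members: Iterable[str]) -> bool:
    """True iff some integer combination over exactly ``members`` is invariant.

    Checks whether the span of the stoichiometric left null space contains a
    vector supported on ``members`` with all-positive coefficients.
    """
    members = set(members)
    _, net_mat = net.stoichiometry()
    idx = [net.species_index(m) for m in members]
    sub = sympy.Matrix(net_mat.astype(int)[idx, :]).T
    # a law supported on `members` only involves member rows, so the
    # restricted left null space decides conservation exactly
    for vec in sub.nullspace():
        if all(x > 0 for x in vec) or all(x < 0 for x in vec):
            return True
    return False


def validate_network(
    net: ReactionNetwork,
    expected_moieties: Sequence[Iterable[str]] | None = None,
) -> ValidationReport:
    """Structural report: conserved totals, dangling species, dead reactions.

    ``expected_moieties`` (each an iterable of species names) are checked
    against the stoichiometry; any expectation the network does not conserve
    is listed in ``violated_moieties``.
    """
    moieties = net.conserved_moieties()
    used = {nm for rx in net.reactions for nm in (*rx.reactants, *rx.products)}
    dangling = tuple(n for n in net.species_names if n not in used)
    dead = tuple(
        rx.label for rx in net.reactions if rx.kf == 0 and (rx.kr in (None, 0.0))
    )
    violated: list[frozenset[str]] = []
    for exp in expected_moieties or ():
        if not moiety_is_conserved(net, exp):
            violated.append(frozenset(exp))
    return ValidationReport(
        conserved_moieties=tuple(moieties),
        dangling_species=dangling,
        zero_rate_reactions=dead,
        violated_moieties=tuple(violated),
    )


# ---------------------------------------------------------------------------
# the reduced fixture network


#: rate constants of the reduced fixture (units: per-s, per-nM per-s, nM per-s)
FIXTURE_RATES: dict[str, float] = {
    "ca_source": 25.0,       # nM/s      basal influx; with ca_clear gives 50 nM
    "ca_clear": 0.5,         # /s        pump/buffer lump (τ = 2 s transients)
    "camp_source": 3.0,      # nM/s      basal synthesis; with camp_clear gives 30 nM
    "camp_clear": 0.1,       # /s        PDE lump
    "gbg_clear": 0.05,       # /s        Giβγ decay (basal 0)
    "ck_act": 2.0e-4,        # /nM/s     Ca·CaM-like first phosphorylation
    "ck_auto": 2.5e-3,       # /nM/s     pCK autophosphorylation feedback
    "pp_bind_f": 1.0,        # /nM/s     PP + pCK association
    "pp_bind_r": 0.1,        # /s        complex dissociation
    "pp_cat": 0.2,           # /s        dephosphorylation, Vmax = 0.2·PPtot
    "gef_act": 2.0e-4,       # /nM/s     cAMP activates GEF (Epac-like)
    "gef_deact": 0.1,        # /s
    "gt_act_gef": 1.0e-3,    # /nM/s     GEFa loads the shared GTPase pool
    "gt_act_gbg": 1.0e-3,    # /nM/s     Gβγ branch, same substrate
    "gt_act_ck": 4.0e-4,     # /nM/s     switch output into the same pool
    "gt_act_ca": 2.0e-5,     # /nM/s     graded RasGRF-like calcium arm
    "gt_hyd": 0.1,           # /s        intrinsic + GAP hydrolysis
    "erk_act": 2.0e-3,       # /nM/s     GtGTP phosphorylates ERK (lumped dual step)
    "erk_deact": 0.05,       # /s        MKP-like dephosphorylation
}

#: initial concentrations (nM) of the fixture before equilibration
FIXTURE_CONCENTRATIONS: dict[str, float] = {
    "Ca": 50.0,
    "cAMP": 30.0,
    "Gbg": 0.0,
    "CK": 100.0,
    "pCK": 0.0,
    "PP": 20.0,
    "PPpCK": 0.0,
    "GEF": 100.0,
    "GEFa": 0.0,
    "GtGDP": 100.0,
    "GtGTP": 0.0,
    "ERK": 240.0,
    "ppERK": 0.0,
}


def build_fixture_network(
    volume: float = 4.0,
    pp_concentration: float | None = None,
) -> ReactionNetwork:
    """Reduced stand-in network with the full model's structural motifs.

    Three clampable inputs (Ca, cAMP, Gbg) drive:

    a. an ultrasensitive kinase switch — CK autophosphorylates (pCK) and is
       dephosphorylated by a small saturable phosphatase pool PP, so pCK
       shows a calcium threshold and outlasts the stimulus;
    b. a linear branch — cAMP activates a GEF which loads a GTPase pool
       whose active form (GtGTP) phosphorylates ERK;
    c. competition — the Gbg branch and the GEF branch (and the switch)
       all draw on the same inactive GTPase pool GtGDP, so combined
       stimulation sums sublinearly.

    ``pp_concentration`` overrides the phosphatase pool (the fixture
    analogue of varying PP1 relative to CaMKII).
    """
    conc = dict(FIXTURE_CONCENTRATIONS)
    if pp_concentration is not None:
        conc["PP"] = float(pp_concentration)
    k = FIXTURE_RATES
    roles = {
        "Ca": "input", "cAMP": "input", "Gbg": "input",
        "CK": "kinase", "pCK": "kinase", "PP": "phosphatase",
        "PPpCK": "phosphatase", "GEF": "gef", "GEFa": "gef",
        "GtGDP": "gtpase", "GtGTP": "gtpase", "ERK": "kinase", "ppERK": "kinase",
    }
    species = tuple(
        SpeciesSpec(name, conc[name], roles[name]) for name in FIXTURE_CONCENTRATIONS
    )
    rx = [
        ReactionSpec("ca_source", (), ("Ca",), k["ca_source"]),
        ReactionSpec("ca_clear", ("Ca",), (), k["ca_clear"]),
        ReactionSpec("camp_source", (), ("cAMP",), k["camp_source"]),
        ReactionSpec("camp_clear", ("cAMP",), (), k["camp_clear"]),
        ReactionSpec("gbg_clear", ("Gbg",), (), k["gbg_clear"]),
        ReactionSpec("ck_act", ("Ca", "CK"), ("Ca", "pCK"), k["ck_act"]),
        ReactionSpec("ck_auto", ("pCK", "CK"), ("pCK", "pCK"), k["ck_auto"]),
        ReactionSpec("pp_bind", ("PP", "pCK"), ("PPpCK",), k["pp_bind_f"], k["pp_bind_r"]),
        ReactionSpec("pp_cat", ("PPpCK",), ("PP", "CK"), k["pp_cat"]),
        ReactionSpec("gef_act", ("cAMP", "GEF"), ("cAMP", "GEFa"), k["gef_act"]),
        ReactionSpec("gef_deact", ("GEFa",), ("GEF",), k["gef_deact"]),
        ReactionSpec("gt_act_gef", ("GEFa", "GtGDP"), ("GEFa", "GtGTP"), k["gt_act_gef"]),
        ReactionSpec("gt_act_gbg", ("Gbg", "GtGDP"), ("Gbg", "GtGTP"), k["gt_act_gbg"]),
        ReactionSpec("gt_act_ck", ("pCK", "GtGDP"), ("pCK", "GtGTP"), k["gt_act_ck"]),
        ReactionSpec("gt_act_ca", ("Ca", "GtGDP"), ("Ca", "GtGTP"), k["gt_act_ca"]),
        ReactionSpec("gt_hyd", ("GtGTP",), ("GtGDP",), k["gt_hyd"]),
        ReactionSpec("erk_act", ("GtGTP", "ERK"), ("GtGTP", "ppERK"), k["erk_act"]),
        ReactionSpec("erk_deact", ("ppERK",), ("ERK",), k["erk_deact"]),
    ]
    return ReactionNetwork(
        species=species,
        reactions=tuple(rx),
        compartment_volume=volume,
        metadata={"fixture": True, "name": "reduced-fixture"},
    )


def fixture_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The fixture's parameter tables in the native tabular schema."""
    return build_fixture_network().to_tables()


def network_from_strings(species_tsv: str, reactions_tsv: str, **kw) -> ReactionNetwork:
    """Convenience loader from in-memory TSV text (used by tests/examples)."""
    sp = pd.read_csv(io.StringIO(species_tsv), sep="\t", dtype=str, keep_default_na=False)
    rx = pd.read_csv(io.StringIO(reactions_tsv), sep="\t", dtype=str, keep_default_na=False)
    return load_network(sp, [rx], **kw)
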