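"""Biochemical reaction networks compiled to mass-action / Michaelis-Menten ODEs.

This module is deliberately generic: it knows nothing about endothelial
signalling.  A :class:`ReactionNetwork` is an ordered collection of
:class:`Species` and :class:`Reaction` objects that compiles to a fast
right-hand side ``dy/dt = S @ v(y)`` where ``S`` is the stoichiometry matrix
and ``v`` the per-reaction flux vector.  Units are micromolar (uM) for
concentrations and seconds for time throughout; reporting layers may convert
to minutes.

The flux kernel is written so that it also works on *complex* state vectors,
which lets sensitivity analysis push a complex-step perturbation through the
integrator without a separate code path.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Species",
    "RateLaw",
    "Reaction",
    "ReactionNetwork",
    "NetworkError",
    "MASS_ACTION_REVERSIBLE",
    "MASS_ACTION_IRREVERSIBLE",
    "MICHAELIS_MENTEN",
]

MASS_ACTION_REVERSIBLE = "mass_action_reversible"
MASS_ACTION_IRREVERSIBLE = "mass_action_irreversible"
MICHAELIS_MENTEN = "michaelis_menten"

_FORMS = (MASS_ACTION_REVERSIBLE, MASS_ACTION_IRREVERSIBLE, MICHAELIS_MENTEN)


class NetworkError(ValueError):
    """Structural or configuration error in a reaction network."""


@dataclass
class Species:
    """One molecular species.

    Parameters
    ----------
    id : str
        Short unique token, e.g. ``"Ca_i"`` or ``"ppMLC"``.
    display_name : str
        Human-readable name for listings and SBML export.
    initial_concentration : float
        Initial concentration in uM, must be >= 0.
    is_boundary : bool
        If True the concentration is clamped (zero time derivative); used
        for reservoir species.  Defaults to False, i.e. ordinary dynamics.
    """

    id: str
    display_name: str = ""
    initial_concentration: float = 0.0
    is_boundary: bool = False

    def __post_init__(self) -> None:
        if not self.display_name:
            self.display_name = self.id
        if self.initial_concentration < 0:
            raise NetworkError(
                f"species {self.id!r}: negative initial concentration"
            )


@dataclass
class RateLaw:
    """Kinetic law of one reaction.

    ``mass_action_*`` use ``kf`` (and ``kb`` when reversible) with per-uM
    powers per second according to the stoichiometry.  ``michaelis_menten``
    uses ``kcat`` (1/s) and ``Km`` (uM) with an explicit enzyme species on
    the reaction.
    """

    form: str = MASS_ACTION_IRREVERSIBLE
    kf: float = 0.0
    kb: float = 0.0
    kcat: float = 0.0
    Km: float | None = None

    def __post_init__(self) -> None:
        if self.form not in _FORMS:
            raise NetworkError(f"unknown rate-law form {self.form!r}")
        for name in ("kf", "kb", "kcat"):
            if getattr(self, name) < 0:
                raise NetworkError(f"rate constant {name} must be >= 0")
        if self.form == MICHAELIS_MENTEN:
            if self.Km is None or self.Km <= 0:
                raise NetworkError("michaelis_menten requires Km > 0")
        if self.form == MASS_ACTION_IRREVERSIBLE and self.kb != 0:
            raise NetworkError("irreversible mass action must have kb == 0")

    @property
    def constants(self) -> dict[str, float]:
        if self.form == MICHAELIS_MENTEN:
            return {"kcat": self.kcat, "Km": self.Km}
        if self.form == MASS_ACTION_REVERSIBLE:
            return {"kf": self.kf, "kb": self.kb}
        return {"kf": self.kf}


@dataclass
class Reaction:
    """One reaction: reactants -> products, with an optional enzyme.

    ``reactants`` / ``products`` are lists of ``(species_id, stoichiometric
    coefficient)`` with integer coefficients >= 1.  ``tags`` carries cascade
    labels (e.g. ``"rock_dependent"``) used by switch-off experiments.
    ``param_names`` optionally maps rate-law constants ("kf", "kb", ...) to
    the names of the model-level parameters they were built from, which
    lets sensitivity analysis aggregate reactions sharing one constant.
    """

    id: str
    reactants: list[tuple[str, int]] = field(default_factory=list)
    products: list[tuple[str, int]] = field(default_factory=list)
    enzyme: str | None = None
    rate_law: RateLaw = field(default_factory=RateLaw)
    tags: frozenset[str] = field(default_factory=frozenset)
    param_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tags = frozenset(self.tags)
        for side in (self.reactants, self.products):
            for sp, coef in side:
                if coef < 1 or int(coef) != coef:
                    raise NetworkError(
                        f"reaction {self.id!r}: stoichiometric coefficient "
                        f"for {sp!r} must be an integer >= 1"
                    )
        if self.rate_law.form == MICHAELIS_MENTEN:
            if self.enzyme is None:
                raise NetworkError(
                    f"reaction {self.id!r}: michaelis_menten needs an enzyme"
                )
            if len(self.reactants) != 1 or self.reactants[0][1] != 1:
                raise NetworkError(
                    f"reaction {self.id!r}: michaelis_menten expects exactly "
                    "one substrate with coefficient 1"
                )


class ReactionNetwork:
    """Ordered species + reactions, compiled to a derivative function.

    The compiled representation uses flat index arrays and
    ``np.multiply.reduceat`` so that one flux evaluation costs microseconds
    and works unchanged for complex-valued states.
    """

    def __init__(self, species: list[Species], reactions: list[Reaction]):
        ids = [s.id for s in species]
        if len(set(ids)) != len(ids):
            raise NetworkError("duplicate species ids")
        rids = [r.id for r in reactions]
        if len(set(rids)) != len(rids):
            raise NetworkError("duplicate reaction ids")
        self.species = list(species)
        self.reactions = list(reactions)
        self._index = {s.id: i for i, s in enumerate(self.species)}
        self._rindex = {r.id: j for j, r in enumerate(self.reactions)}
        for r in self.reactions:
            for sp, _ in list(r.reactants) + list(r.products):
                if sp not in self._index:
                    raise NetworkError(
                        f"reaction {r.id!r} references unknown species {sp!r}"
                    )
            if r.enzyme is not None and r.enzyme not in self._index:
                raise NetworkError(
                    f"reaction {r.id!r} has unknown enzyme {r.enzyme!r}"
                )
        self._compiled = None
        self._moieties = None

    # -- basic views ------------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self, species_id: str) -> int:
        try:
            return self._index[species_id]
        except KeyError:
            raise NetworkError(f"unknown species {species_id!r}") from None

    def reaction(self, reaction_id: str) -> Reaction:
        try:
            return self.reactions[self._rindex[reaction_id]]
        except KeyError:
            raise NetworkError(f"unknown reaction {reaction_id!r}") from None

    @property
    def tag_vocabulary(self) -> frozenset[str]:
        vocab: set[str] = set()
        for r in self.reactions:
            vocab |= r.tags
        return frozenset(vocab)

    def initial_state(self) -> np.ndarray:
        return np.array(
            [s.initial_concentration for s in self.species], dtype=float
        )

    # -- parameter table --------------------------------------------------

    @property
    def parameters(self) -> dict[tuple[str, str], float]:
        """Mapping ``(reaction id, constant name) -> value``."""
        table: dict[tuple[str, str], float] = {}
        for r in self.reactions:
            for name, value in r.rate_law.constants.items():
                table[(r.id, name)] = value
        return table

    def set_parameter(self, reaction_id: str, name: str, value: float) -> None:
        rl = self.reaction(reaction_id).rate_law
        if name not in rl.constants:
            raise NetworkError(
                f"reaction {reaction_id!r} has no constant {name!r}"
            )
        setattr(rl, name, value)
        rl.__post_init__()
        self._compiled = None

    # -- structure ---------------------------------------------------------

    def stoichiometry_matrix(self) -> np.ndarray:
        """Integer matrix ``S[i, j]`` = net production of species i in
        reaction j (products minus reactants)."""
        S = np.zeros((self.n_species, self.n_reactions), dtype=int)
        for j, r in enumerate(self.reactions):
            for sp, coef in r.reactants:
                S[self._index[sp], j] -= coef
            for sp, coef in r.products:
                S[self._index[sp], j] += coef
        return S

    def conserved_moieties(self) -> list[np.ndarray]:
        """Integer weight vectors v with ``v @ S == 0`` (left null space).

        Computed by exact rational elimination (sympy), then scaled to the
        smallest integer representation.  Each vector is a conservation
        relation, e.g. total-MLC or total-calmodulin pools.
        """
        if self._moieties is None:
            import sympy

            S = sympy.Matrix(self.stoichiometry_matrix())
            basis = S.T.nullspace()
            out = []
            for v in basis:
                denoms = [sympy.fraction(x)[1] for x in v]
                scale = sympy.lcm(denoms) if denoms else 1
                w = (v * scale).T.tolist()[0]
                g = sympy.gcd([x for x in w if x != 0] or [1])
                w = [int(x / g) for x in w]
                if sum(w) < 0:
                    w = [-x for x in w]
                out.append(np.array(w, dtype=int))
            self._moieties = out
        return [v.copy() for v in self._moieties]

    # -- compilation & evaluation -----------------------------------------

    def _compile(self):
        if self._compiled is not None:
            return self._compiled
        nr = self.n_reactions
        f_flat: list[int] = []
        f_starts: list[int] = []
        f_rows: list[int] = []
        b_flat: list[int] = []
        b_starts: list[int] = []
        b_rows: list[int] = []
        # constants may be complex during complex-step sensitivity runs
        cdtype = np.result_type(
            float,
            *(np.asarray(v).dtype for r in self.reactions
              for v in r.rate_law.constants.values() if v is not None),
        )
        kf = np.zeros(nr, dtype=cdtype)
        kb = np.zeros(nr, dtype=cdtype)
        mm = np.zeros(nr, dtype=bool)
        kcat = np.zeros(nr, dtype=cdtype)
        Km = np.ones(nr, dtype=cdtype)
        enz = np.zeros(nr, dtype=int)
        sub = np.zeros(nr, dtype=int)
        for j, r in enumerate(self.reactions):
            rl = r.rate_law
            if rl.form == MICHAELIS_MENTEN:
                mm[j] = True
                kcat[j] = rl.kcat
                Km[j] = rl.Km
                enz[j] = self._index[r.enzyme]
                sub[j] = self._index[r.reactants[0][0]]
                continue
            kf[j] = rl.kf
            kb[j] = rl.kb
            idx = [self._index[sp] for sp, c in r.reactants for _ in range(c)]
            if idx:
                f_rows.append(j)
                f_starts.append(len(f_flat))
                f_flat.extend(idx)
            if rl.form == MASS_ACTION_REVERSIBLE:
                idx = [
                    self._index[sp] for sp, c in r.products for _ in range(c)
                ]
                if idx:
                    b_rows.append(j)
                    b_starts.append(len(b_flat))
                    b_flat.extend(idx)
        S = self.stoichiometry_matrix().astype(float)
        boundary = np.array([s.is_boundary for s in self.species])
        S_eff = S.copy()
        S_eff[boundary, :] = 0.0
        self._compiled = dict(
            f_flat=np.array(f_flat, dtype=int),
            f_starts=np.array(f_starts, dtype=int),
            f_rows=np.array(f_rows, dtype=int),
            b_flat=np.array(b_flat, dtype=int),
            b_starts=np.array(b_starts, dtype=int),
            b_rows=np.array(b_rows, dtype=int),
            kf=kf,
            kb=kb,
            mm=mm,
            kcat=kcat,
            Km=Km,
            enz=enz,
            sub=sub,
            S=S,
            S_eff=S_eff,
        )
        return self._compiled

    def flux_vector(self, state: np.ndarray, check: bool = True) -> np.ndarray:
        """Per-reaction flux (uM/s) at the given state.

        Mass action: ``kf * prod([reactants]) - kb * prod([products])``;
        Michaelis-Menten: ``kcat * [E] * [S] / (Km + [S])``.

        With ``check=True`` (the default, for direct calls) a negative
        concentration raises; the ODE right-hand side disables the check
        because adaptive solvers probe trial states that undershoot zero
        by up to the absolute tolerance.
        """
        state = np.asarray(state)
        if check and not np.iscomplexobj(state) and np.any(state < 0):
            raise NetworkError(
                f"negative concentration in state (min={np.min(state):g})"
            )
        c = self._compile()
        flux = np.zeros(
            self.n_reactions,
            dtype=np.result_type(state.dtype, c["kf"].dtype, float),
        )
        if c["f_rows"].size:
            fwd = np.multiply.reduceat(state[c["f_flat"]], c["f_starts"])
            flux[c["f_rows"]] = c["kf"][c["f_rows"]] * fwd
        if c["b_rows"].size:
            back = np.multiply.reduceat(state[c["b_flat"]], c["b_starts"])
            flux[c["b_rows"]] -= c["kb"][c["b_rows"]] * back
        if np.any(c["mm"]):
            m = c["mm"]
            s = state[c["sub"][m]]
            e = state[c["enz"][m]]
            flux[m] = c["kcat"][m] * e * s / (c["Km"][m] + s)
        return flux

    def rhs(self, t: float, state: np.ndarray) -> np.ndarray:
        """ODE right-hand side ``d(state)/dt`` at time ``t`` (autonomous)."""
        c = self._compile()
        return c["S_eff"] @ self.flux_vector(state, check=False)

    # -- experiments -------------------------------------------------------

    def apply_switch(self, switches: dict[str, bool]) -> "ReactionNetwork":
        """Return a copy with cascades switched on/off.

        Every reaction carrying a label mapped to False has all its rate
        constants set to zero; structure is otherwise untouched.  Idempotent,
        and commutes across disjoint label sets.
        """
        vocab = self.tag_vocabulary
        unknown = set(switches) - set(vocab)
        if unknown:
            raise NetworkError(f"unknown cascade labels: {sorted(unknown)}")
        off = {label for label, on in switches.items() if not on}
        net = self.copy()
        for r in net.reactions:
            if r.tags & off:
                rl = r.rate_law
                rl.kf = 0.0
                rl.kb = 0.0
                rl.kcat = 0.0
        net._compiled = None
        return net

    def copy(self) -> "ReactionNetwork":
        return ReactionNetwork(
            [replace(s) for s in self.species],
            [
                Reaction(
                    id=r.id,
                    reactants=list(r.reactants),
                    products=list(r.products),
                    enzyme=r.enzyme,
                    rate_law=copy.copy(r.rate_law),
                    tags=r.tags,
                    param_names=dict(r.param_names),
                )
                for r in self.reactions
            ],
        )

    # -- listing ------------------------------------------------------------

    def to_text(self) -> str:
        """Plain one-reaction-per-line listing for review and diffing."""
        lines = []
        for r in self.reactions:
            lhs = " + ".join(
                (f"{c} {sp}" if c > 1 else sp) for sp, c in r.reactants
            ) or "0"
            rhs = " + ".join(
                (f"{c} {sp}" if c > 1 else sp) for sp, c in r.products
            ) or "0"
            arrow = "<->" if r.rate_law.form == MASS_ACTION_REVERSIBLE else "->"
            consts = ", ".join(
                f"{k}={v:g}" for k, v in r.rate_law.constants.items()
            )
            enz = f" @{r.enzyme}" if r.enzyme else ""
            tags = ",".join(sorted(r.tags))
            lines.append(
                f"{r.id}: {lhs} {arrow} {rhs}{enz} ; {consts} ; tags={tags}"
            )
        return "\n".join(lines) + "\n"
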