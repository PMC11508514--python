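"""Ancestral-state reconstruction of discrete characters on a rooted tree.

Two standard approaches are provided for binary (or generally k-state)
characters such as the scoliid gene-rearrangement cluster modes:

* **maximum parsimony** — the Fitch/Hartigan dynamic program, returning
  per-node state sets and the minimal number of changes;
* **maximum likelihood** — continuous-time Markov models of character
  evolution: the one-parameter symmetric Mk1 model and, for two states,
  the two-parameter asymmetric AsymmMk model.  Likelihoods come from
  Felsenstein's pruning algorithm, rates are fitted by bounded
  optimisation on the log scale, models are compared by AIC
  (``2·n_params − 2·lnL``) and marginal posterior state probabilities at
  internal nodes are obtained by the standard inside/outside pass.

Missing tip data contribute a partial likelihood of 1 for every state
(maximum parsimony: the full state set), so unscored taxa are carried,
not dropped.

The modelling interface follows the model/results idiom: build an
:class:`MkModel` from a tree and tip states, call :meth:`MkModel.fit`,
and read estimates, lnL, AIC and reconstructions off the returned
:class:`MkResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "MISSING",
    "CharacterMatrix",
    "FitchResult",
    "fitch",
    "mk_transition_matrix",
    "pruning_loglik",
    "MkModel",
    "MkResults",
    "AncestralReconstruction",
    "fit_model",
    "marginal_reconstruction",
    "select_model",
    "node_signature",
]

MISSING = "?"

RATE_BOUNDS = (1e-8, 1e3)


def node_signature(node: dendropy.Node) -> str:
    """Stable node key: the sorted labels of the tips it subtends."""
    tips = sorted(lf.taxon.label for lf in node.leaf_iter() if lf.taxon)
    return "|".join(tips)


class _TreeIndex:
    """Postorder arrays of a dendropy tree for fast repeated traversals."""

    def __init__(self, tree: dendropy.Tree, require_lengths: bool = True):
        self.nodes = list(tree.postorder_node_iter())
        idx = {id(n): i for i, n in enumerate(self.nodes)}
        self.children = [[idx[id(c)] for c in n.child_nodes()] for n in self.nodes]
        self.is_leaf = [not ch for ch in self.children]
        self.labels = [n.taxon.label if n.taxon else None for n in self.nodes]
        self.root = len(self.nodes) - 1
        self.blen = []
        for n in self.nodes:
            L = n.edge.length
            if L is None:
                if idx[id(n)] != self.root and require_lengths:
                    raise ValueError(
                        f"node {self.labels[idx[id(n)]] or node_signature(n)} has no branch "
                        "length; pass default_branch_length to read_newick or set unit lengths"
                    )
                L = 0.0
            if L < 0:
                raise ValueError("negative branch length")
            self.blen.append(float(L))
        self.signatures = [node_signature(n) for n in self.nodes]

    @property
    def tip_labels(self) -> list[str]:
        return [l for l, leaf in zip(self.labels, self.is_leaf) if leaf]


def _tree_index(tree: dendropy.Tree, require_lengths: bool = True) -> _TreeIndex:
    """Memoised :class:`_TreeIndex`; rebuilt if the tree's node count changes."""
    attr = "_mitoscolia_index" if require_lengths else "_mitoscolia_index_nolen"
    cached = getattr(tree, attr, None)
    if cached is not None and len(cached.nodes) == sum(1 for _ in tree.postorder_node_iter()):
        return cached
    ti = _TreeIndex(tree, require_lengths=require_lengths)
    setattr(tree, attr, ti)
    return ti


def _branch_matrices(family: str, rates, blen: np.ndarray, k: int) -> np.ndarray:
    """Stack of per-branch transition matrices, shape (n_branches, k, k)."""
    t = np.asarray(blen, dtype=float)
    if family == "Mk1":
        q = float(np.atleast_1d(rates)[0])
        e = np.exp(-k * q * t)
        P = np.empty((len(t), k, k))
        P[:] = ((1.0 - e) / k)[:, None, None]
        idx = np.arange(k)
        P[:, idx, idx] = (1.0 / k + (k - 1) / k * e)[:, None]
        return P
    if family == "AsymmMk":
        q01, q10 = (float(r) for r in rates)
        tot = q01 + q10
        if tot == 0:
            return np.tile(np.eye(2), (len(t), 1, 1))
        pi0, pi1 = q10 / tot, q01 / tot
        e = np.exp(-tot * t)
        P = np.empty((len(t), 2, 2))
        P[:, 0, 0] = pi0 + pi1 * e
        P[:, 0, 1] = pi1 * (1 - e)
        P[:, 1, 0] = pi0 * (1 - e)
        P[:, 1, 1] = pi1 + pi0 * e
        return P
    raise ValueError(f"unknown model family {family!r}")


# --- character matrices -------------------------------------------------------

@dataclass
class CharacterMatrix:
    """Taxon x character table of discrete states with explicit missing data."""

    taxa: list[str]
    characters: dict[str, tuple[str, ...]]  # name -> alphabet
    states: dict[str, dict[str, str | None]]  # taxon -> {character: state}

    def __post_init__(self):
        if len(self.taxa) != len(set(self.taxa)):
            raise ValueError("duplicate taxa")
        for taxon, row in self.states.items():
            for char, st in row.items():
                if st is not None and st != MISSING and st not in self.characters[char]:
                    raise ValueError(f"{taxon}: state {st!r} not in alphabet of {char}")

    def column(self, character: str) -> dict[str, str | None]:
        """Tip states of one character; missing coded as None."""
        out = {}
        for taxon in self.taxa:
            st = self.states.get(taxon, {}).get(character)
            out[taxon] = None if st in (None, MISSING, "") else st
        return out

    @classmethod
    def from_tsv(cls, path: str | Path,
                 alphabets: Mapping[str, Sequence[str]] | None = None) -> "CharacterMatrix":
        """Read a modes table (first column taxon, one column per character, ``?`` = missing)."""
        df = pd.read_csv(path, sep="\t", dtype=str).fillna(MISSING)
        taxon_col = df.columns[0]
        chars = list(df.columns[1:])
        characters = {}
        for c in chars:
            if alphabets and c in alphabets:
                characters[c] = tuple(alphabets[c])
            else:
                observed = sorted(set(df[c]) - {MISSING, ""})
                characters[c] = tuple(observed)
        states = {row[taxon_col]: {c: (None if row[c] in (MISSING, "") else row[c]) for c in chars}
                  for _, row in df.iterrows()}
        return cls(taxa=list(df[taxon_col]), characters=characters, states=states)

    def to_tsv(self, path: str | Path, taxon_col: str = "taxon") -> None:
        rows = [{taxon_col: t, **{c: (self.states[t].get(c) or MISSING) for c in self.characters}}
                for t in self.taxa]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --- maximum parsimony --------------------------------------------------------

@dataclass
class FitchResult:
    """State sets and minimal change count from the Fitch/Hartigan pass."""

    alphabet: tuple[str, ...]
    node_sets: dict[str, frozenset]  # node signature -> state set
    changes: int
    root_signature: str

    @property
    def root_set(self) -> frozenset:
        return self.node_sets[self.root_signature]


def fitch(tree: dendropy.Tree, character: Mapping[str, str | None],
          alphabet: Sequence[str] | None = None) -> FitchResult:
    """Minimal-change (Fitch; Hartigan at polytomies) state sets on a rooted tree.

    Missing tips carry the full state set and never force a change.
    """
    if alphabet is None:
        alphabet = tuple(sorted({s for s in character.values() if s not in (None, MISSING)}))
    full = frozenset(alphabet)
    if not full:
        raise ValueError("all tips missing: no observed states")
    ti = _tree_index(tree, require_lengths=False)
    observed = 0
    sets: list[frozenset] = [frozenset()] * len(ti.nodes)
    changes = 0
    for i, node in enumerate(ti.nodes):
        if ti.is_leaf[i]:
            st = character.get(ti.labels[i])
            if st in (None, MISSING):
                sets[i] = full
            else:
                if st not in full:
                    raise ValueError(f"tip {ti.labels[i]}: state {st!r} not in alphabet")
                sets[i] = frozenset({st})
                observed += 1
        else:
            kids = [sets[c] for c in ti.children[i]]
            count = {s: sum(1 for k in kids if s in k) for s in full}
            top = max(count.values())
            sets[i] = frozenset(s for s, c in count.items() if c == top)
            changes += len(kids) - top
    if observed == 0:
        raise ValueError("all tips missing: no observed states")
    node_sets = {sig: sets[i] for i, sig in enumerate(ti.signatures)}
    return FitchResult(alphabet=tuple(alphabet), node_sets=node_sets,
                       changes=changes, root_signature=ti.signatures[ti.root])


# --- Mk likelihood ------------------------------------------------------------

def mk_transition_matrix(family: str, rates, t: float, k: int = 2) -> np.ndarray:
    """Transition probability matrix over a branch of length ``t``.

    Mk1: all states exchange at one rate ``q``;
    ``P_ii = 1/k + (k-1)/k·exp(-k·q·t)``, ``P_ij = 1/k - 1/k·exp(-k·q·t)``.
    AsymmMk (k=2): rates ``(q01, q10)`` with the standard two-state
    closed form.  Rows sum to 1.
    """
    if t < 0:
        raise ValueError("negative branch length")
    if family == "Mk1":
        q = float(np.atleast_1d(rates)[0])
        if q < 0:
            raise ValueError("rate must be non-negative")
        e = math.exp(-k * q * t)
        P = np.full((k, k), (1.0 - e) / k)
        np.fill_diagonal(P, 1.0 / k + (k - 1) / k * e)
        return P
    if family == "AsymmMk":
        if k != 2:
            raise ValueError("AsymmMk is defined for k=2")
        q01, q10 = (float(r) for r in rates)
        if q01 < 0 or q10 < 0:
            raise ValueError("rates must be non-negative")
        tot = q01 + q10
        if tot == 0:
            return np.eye(2)
        pi0, pi1 = q10 / tot, q01 / tot
        e = math.exp(-tot * t)
        return np.array([[pi0 + pi1 * e, pi1 * (1 - e)],
                         [pi0 * (1 - e), pi1 + pi0 * e]])
    raise ValueError(f"unknown model family {family!r}")


def _default_prior(family: str, rates, k: int) -> np.ndarray:
    if family == "AsymmMk":
        q01, q10 = (float(r) for r in rates)
        tot = q01 + q10
        if tot > 0:
            return np.array([q10 / tot, q01 / tot])
    return np.full(k, 1.0 / k)


def _tip_partials(character: Mapping, alphabet: Sequence[str], k: int) -> dict[str, np.ndarray]:
    """taxon -> (n_chars, k) partial-likelihood rows (all-ones for missing)."""
    state_idx = {s: i for i, s in enumerate(alphabet)}
    out = {}
    for taxon, value in character.items():
        vals = value if isinstance(value, (list, tuple, np.ndarray)) else [value]
        arr = np.ones((len(vals), k))
        for j, v in enumerate(vals):
            if v in (None, MISSING):
                continue
            if isinstance(v, (int, np.integer)):
                idx = int(v)
            else:
                if v not in state_idx:
                    raise ValueError(f"tip {taxon}: state {v!r} not in alphabet {alphabet}")
                idx = state_idx[v]
            arr[j, :] = 0.0
            arr[j, idx] = 1.0
        out[taxon] = arr
    return out


def _up_pass(ti: _TreeIndex, tips: dict[str, np.ndarray], family: str, rates,
             k: int) -> tuple[list, np.ndarray, list]:
    """Inside (post-order) partials, per-node, scaled; returns (partials, logscale, Pmats)."""
    n_chars = next(iter(tips.values())).shape[0]
    partials: list[np.ndarray | None] = [None] * len(ti.nodes)
    Pmats = _branch_matrices(family, rates, ti.blen, k)
    logscale = np.zeros(n_chars)
    for i in range(len(ti.nodes)):
        if ti.is_leaf[i]:
            lbl = ti.labels[i]
            if lbl not in tips:
                raise ValueError(f"tip {lbl!r} has no character assignment")
            partials[i] = tips[lbl]
        else:
            prod = np.ones((n_chars, k))
            for c in ti.children[i]:
                prod = prod * (partials[c] @ Pmats[c].T)
            scale = prod.max(axis=1)
            safe = np.where(scale > 0, scale, 1.0)
            partials[i] = prod / safe[:, None]
            with np.errstate(divide="ignore"):
                logscale = logscale + np.where(scale > 0, np.log(safe), -np.inf)
    return partials, logscale, Pmats


def pruning_loglik(tree: dendropy.Tree, character: Mapping, family: str = "Mk1",
                   rates=1.0, root_prior: np.ndarray | None = None,
                   alphabet: Sequence[str] | None = None, k: int | None = None) -> float:
    """Felsenstein pruning log-likelihood of one (or several) characters.

    ``character`` maps tip label to a state (label, index or None for
    missing), or to a sequence of states for several characters sharing
    the same rates; the summed lnL is returned.  Conflicting data on a
    zero-length tree yields ``-inf`` rather than an exception.
    """
    if alphabet is None:
        obs = set()
        for v in character.values():
            for s in (v if isinstance(v, (list, tuple, np.ndarray)) else [v]):
                if s not in (None, MISSING) and not isinstance(s, (int, np.integer)):
                    obs.add(s)
        alphabet = tuple(sorted(obs)) if obs else tuple(str(i) for i in range(k or 2))
    k = k or len(alphabet)
    ti = _tree_index(tree)
    tips = _tip_partials(character, alphabet, k)
    partials, logscale, _ = _up_pass(ti, tips, family, rates, k)
    prior = _default_prior(family, rates, k) if root_prior is None else np.asarray(root_prior)
    site = partials[ti.root] @ prior
    with np.errstate(divide="ignore"):
        return float(np.sum(np.log(site) + logscale))


# --- model / results objects --------------------------------------------------

class MkModel:
    """Mk-type model of a discrete character on a rooted tree with branch lengths.

    Parameters
    ----------
    tree : dendropy.Tree
        Rooted; every non-root edge needs a length.
    character : mapping
        Tip label -> state (or None/``'?'`` for missing); sequences of
        states fit several characters under shared rates.
    family : {"Mk1", "AsymmMk"}
    alphabet : sequence of str, optional
        State labels; inferred from the data when omitted.
    root_prior : array, optional
        Uniform for Mk1, stationary for AsymmMk by default.
    """

    def __init__(self, tree: dendropy.Tree, character: Mapping, family: str = "Mk1",
                 alphabet: Sequence[str] | None = None,
                 root_prior: np.ndarray | None = None):
        if family not in {"Mk1", "AsymmMk"}:
            raise ValueError(f"unknown model family {family!r}")
        self.tree = tree
        self.family = family
        self.character = dict(character)
        if alphabet is None:
            obs = set()
            for v in self.character.values():
                for s in (v if isinstance(v, (list, tuple, np.ndarray)) else [v]):
                    if s not in (None, MISSING) and not isinstance(s, (int, np.integer)):
                        obs.add(s)
            if not obs:
                raise ValueError("cannot infer alphabet: all tips missing")
            alphabet = tuple(sorted(obs))
        self.alphabet = tuple(alphabet)
        self.k = len(self.alphabet)
        self.root_prior = root_prior
        self._ti = _tree_index(tree)
        self._tips = _tip_partials(self.character, self.alphabet, self.k)
        self.n_params = 1 if family == "Mk1" else 2

    @classmethod
    def from_matrix(cls, tree: dendropy.Tree, matrix: CharacterMatrix,
                    character: str, family: str = "Mk1", **kw) -> "MkModel":
        return cls(tree, matrix.column(character),
                   family=family, alphabet=matrix.characters[character], **kw)

    def loglike(self, rates) -> float:
        partials, logscale, _ = _up_pass(self._ti, self._tips, self.family, rates, self.k)
        prior = (_default_prior(self.family, rates, self.k)
                 if self.root_prior is None else np.asarray(self.root_prior))
        site = partials[self._ti.root] @ prior
        with np.errstate(divide="ignore"):
            return float(np.sum(np.log(site) + logscale))

    def _observed_states(self) -> set:
        obs = set()
        for v in self.character.values():
            for s in (v if isinstance(v, (list, tuple, np.ndarray)) else [v]):
                if s not in (None, MISSING):
                    obs.add(s)
        return obs

    def fit(self, n_starts: int = 3, seed: int = 0,
            bounds: tuple[float, float] = RATE_BOUNDS) -> "MkResults":
        """Maximise the pruning likelihood over rates (log scale, multi-start)."""
        lo, hi = np.log(bounds[0]), np.log(bounds[1])
        rng = np.random.default_rng(seed)

        if self.family == "Mk1":
            def neg(x):
                return -self.loglike(math.exp(x))
            edges = np.linspace(lo, hi, n_starts + 1)
            best = None
            for a, b in zip(edges[:-1], edges[1:]):
                res = optimize.minimize_scalar(neg, bounds=(a, b), method="bounded")
                if best is None or res.fun < best.fun:
                    best = res
            if best is None or not np.isfinite(best.fun):
                raise RuntimeError("Mk1 optimisation failed to converge")
            rates = (math.exp(best.x),)
            llf = -best.fun
        else:
            def neg(x):
                return -self.loglike(np.exp(x))
            starts = [np.array([math.log(0.1)] * 2)]
            starts += [rng.uniform(math.log(1e-3), math.log(10.0), size=2)
                       for _ in range(max(0, n_starts - 1))]
            best = None
            for x0 in starts:
                res = optimize.minimize(neg, x0, method="L-BFGS-B",
                                        bounds=[(lo, hi)] * 2)
                if res.success and (best is None or res.fun < best.fun):
                    best = res
            if best is None:
                raise RuntimeError("AsymmMk optimisation failed to converge from all starts")
            rates = tuple(np.exp(best.x))
            llf = -best.fun

        at_boundary = any(r <= bounds[0] * (1 + 1e-4) or r >= bounds[1] * (1 - 1e-4)
                          for r in rates)
        if len(self._observed_states()) < 2:
            at_boundary = True
        return MkResults(model=self, rates=rates, llf=llf,
                         n_params=self.n_params, at_boundary=at_boundary)


@dataclass
class MkResults:
    """Fitted Mk-type model: rates, lnL, AIC and reconstructions."""

    model: MkModel
    rates: tuple[float, ...]
    llf: float
    n_params: int
    at_boundary: bool = False

    @property
    def family(self) -> str:
        return self.model.family

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.llf

    @property
    def root_prior(self) -> np.ndarray:
        if self.model.root_prior is not None:
            return np.asarray(self.model.root_prior)
        return _default_prior(self.family, self.rates, self.model.k)

    def marginal_probabilities(self) -> dict[str, np.ndarray]:
        """Marginal posterior state probabilities for every node (by signature)."""
        return _marginals(self.model, self.rates, self.root_prior)

    def reconstruction(self) -> "AncestralReconstruction":
        fr = fitch(self.model.tree, _first_character(self.model.character),
                   alphabet=self.model.alphabet)
        return AncestralReconstruction(alphabet=self.model.alphabet,
                                       ml_probabilities=self.marginal_probabilities(),
                                       mp_sets=fr.node_sets, mp_changes=fr.changes,
                                       root_signature=fr.root_signature, fitted=self)

    def summary(self) -> str:
        lines = [
            f"{self.family} model, {self.model.k} states {self.model.alphabet}",
            f"  rates:      " + ", ".join(f"{r:.6g}" for r in self.rates)
            + ("  [at bound]" if self.at_boundary else ""),
            f"  lnL:        {self.llf:.4f}",
            f"  n_params:   {self.n_params}",
            f"  AIC:        {self.aic:.4f}",
            f"  root prior: " + ", ".join(f"{p:.4f}" for p in self.root_prior),
        ]
        return "\n".join(lines)


def _first_character(character: Mapping) -> dict:
    out = {}
    for taxon, v in character.items():
        out[taxon] = v[0] if isinstance(v, (list, tuple, np.ndarray)) else v
    return out


def _marginals(model: MkModel, rates, prior: np.ndarray) -> dict[str, np.ndarray]:
    """Inside/outside marginal posteriors (valid for non-reversible models too)."""
    ti = model._ti
    partials, _, Pmats = _up_pass(ti, model._tips, model.family, rates, model.k)
    n_chars = partials[ti.root].shape[0]
    outside: list[np.ndarray | None] = [None] * len(ti.nodes)
    outside[ti.root] = np.tile(prior, (n_chars, 1))
    for i in range(len(ti.nodes) - 1, -1, -1):
        kids = ti.children[i]
        for c in kids:
            contrib = outside[i].copy()
            for b in kids:
                if b != c:
                    contrib = contrib * (partials[b] @ Pmats[b].T)
            outside[c] = contrib @ Pmats[c]
    out = {}
    for i, sig in enumerate(ti.signatures):
        joint = partials[i] * outside[i]
        total = joint.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            post = np.where(total > 0, joint / np.where(total > 0, total, 1.0), np.nan)
        out[sig] = post[0] if n_chars == 1 else post
    return out


@dataclass
class AncestralReconstruction:
    """Per-node MP state sets and ML marginal probability vectors."""

    alphabet: tuple[str, ...]
    ml_probabilities: dict[str, np.ndarray]
    mp_sets: dict[str, frozenset]
    mp_changes: int
    root_signature: str
    fitted: MkResults | None = None

    def ml_at(self, signature: str) -> dict[str, float]:
        vec = self.ml_probabilities[signature]
        return {s: float(p) for s, p in zip(self.alphabet, np.atleast_1d(vec))}

    def ml_state(self, signature: str) -> str:
        vec = np.atleast_1d(self.ml_probabilities[signature])
        return self.alphabet[int(np.argmax(vec))]

    def to_json_dict(self) -> dict:
        d = {
            "alphabet": list(self.alphabet),
            "mp_changes": self.mp_changes,
            "root": self.root_signature,
            "nodes": {
                sig: {
                    "mp_set": sorted(self.mp_sets[sig]),
                    "ml_probabilities": [float(x) for x in np.atleast_1d(vec)],
                }
                for sig, vec in self.ml_probabilities.items()
            },
        }
        if self.fitted is not None:
            d["model"] = {
                "family": self.fitted.family,
                "rates": list(self.fitted.rates),
                "lnL": self.fitted.llf,
                "aic": self.fitted.aic,
                "at_boundary": self.fitted.at_boundary,
            }
        return d


# --- functional wrappers ------------------------------------------------------

def fit_model(tree: dendropy.Tree, character: Mapping, family: str = "Mk1",
              alphabet: Sequence[str] | None = None, seed: int = 0,
              root_prior: np.ndarray | None = None) -> MkResults:
    """Fit one model family to one character; see :class:`MkModel`."""
    return MkModel(tree, character, family=family, alphabet=alphabet,
                   root_prior=root_prior).fit(seed=seed)


def marginal_reconstruction(tree: dendropy.Tree, character: Mapping,
                            fitted: MkResults) -> AncestralReconstruction:
    """Marginal ML + Fitch MP reconstruction of a character under a fitted model."""
    model = MkModel(tree, character, family=fitted.family,
                    alphabet=fitted.model.alphabet, root_prior=fitted.model.root_prior)
    res = MkResults(model=model, rates=fitted.rates, llf=fitted.llf,
                    n_params=fitted.n_params, at_boundary=fitted.at_boundary)
    return res.reconstruction()


def select_model(fits: Sequence[MkResults]) -> MkResults:
    """Minimum-AIC fit; ties go to the model with fewer parameters."""
    if not fits:
        raise ValueError("no fitted models to select from")
    return min(fits, key=lambda f: (round(f.aic, 12), f.n_params))
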