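"""The Q structural-similarity order parameter and native-contact analysis.

Q compares the internal Cα distance set of a conformation with that of a
reference (native) structure:

    Q = (1/N) Σ_pairs exp[ −(r_ij − r_ij^N)² / (2 σ_ij²) ]

summed over residue pairs with sequence separation |i − j| ≥ 3 within a
chain, plus (depending on mode) pairs across chains.  Q is 1 for the native
structure itself and decays towards 0 as internal distances deviate; being
built from distances only, it is invariant under rigid motion of the whole
conformation.

Three pair subsets are exposed:

* ``monomer`` — intra-chain pairs only: how well each monomer is folded;
* ``dimer``   — intra-chain plus all inter-chain pairs;
* ``interface`` — inter-chain pairs only, restricted to pairs that are close
  (≤ ``interface_native_cutoff``) in the native structure: nativeness of the
  binding interface independent of monomer folding.  A dimer whose monomers
  are perfectly folded but docked the wrong way (e.g. the inverted handshake)
  scores high monomer Q and near-zero interface Q.

The pair width grows weakly with sequence separation for intra-chain pairs,
σ_ij = σ0 (1 + |i − j|)^ε with ε = 0.15 by default, the convention used by
coarse-grained folding models; separation is meaningless across chains, so
inter-chain pairs use the constant σ0 (1 + s_min)^ε.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structio import Structure

__all__ = [
    "QSpec",
    "ContactReference",
    "build_contact_reference",
    "q_score",
    "q_score_best",
    "fraction_native_contacts",
    "contact_map",
]

_MODES = ("monomer", "dimer", "interface")


@dataclass(frozen=True)
class QSpec:
    """Configuration of the Q pair set and widths."""

    mode: str = "dimer"
    sigma_exponent: float = 0.15
    sigma_base: float = 1.0  # Å
    interface_native_cutoff: float = 9.5  # Å; np.inf for the all-pairs variant
    min_separation: int = 3

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.sigma_base <= 0 or self.sigma_exponent < 0:
            raise ValueError("sigma_base must be > 0 and sigma_exponent >= 0")
        if self.interface_native_cutoff <= 0:
            raise ValueError("interface_native_cutoff must be > 0")
        if self.min_separation < 1:
            raise ValueError("min_separation must be >= 1")


@dataclass
class ContactReference:
    """The native pair list with reference distances and widths.

    ``pairs`` rows are (chain_a, i, chain_b, j) with i, j internal 0-based
    residue indices; ``pair_class`` is 'intra' or 'inter' per pair.
    """

    pairs: list[tuple[str, int, str, int]]
    native_distance: np.ndarray  # Å
    sigma: np.ndarray  # Å
    pair_class: list[str]
    spec: QSpec = field(default_factory=QSpec)

    def __post_init__(self):
        self.native_distance = np.asarray(self.native_distance, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = len(self.pairs)
        if not (len(self.native_distance) == n == len(self.sigma) == len(self.pair_class)):
            raise ValueError("pair list and per-pair arrays have different lengths")
        if n == 0:
            raise ValueError("contact reference is empty")
        if np.any(self.sigma <= 0) or np.any(self.native_distance <= 0):
            raise ValueError("all sigma and native distances must be positive")
        for (ca, i, cb, j), cls in zip(self.pairs, self.pair_class):
            if cls == "intra" and abs(j - i) < self.spec.min_separation:
                raise ValueError(
                    f"intra pair ({ca},{i})-({cb},{j}) violates minimum "
                    f"sequence separation {self.spec.min_separation}"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain_a": [p[0] for p in self.pairs],
                "i": [p[1] for p in self.pairs],
                "chain_b": [p[2] for p in self.pairs],
                "j": [p[3] for p in self.pairs],
                "r_native": self.native_distance,
                "sigma": self.sigma,
                "class": self.pair_class,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_contact_reference(native: Structure, spec: QSpec = QSpec()) -> ContactReference:
    """Enumerate the native pair list for a Q calculation.

    monomer: all intra-chain pairs with separation ≥ min_separation;
    dimer: those plus all inter-chain pairs;
    interface: inter-chain pairs with native distance ≤ interface_native_cutoff.
    """
    if spec.mode in ("dimer", "interface") and len(native.chains) < 2:
        raise ValueError(f"{spec.mode!r} mode requires at least 2 chains")
    if spec.mode == "monomer" and not any(
        len(c) > spec.min_separation for c in native.chains
    ):
        raise ValueError(
            "monomer mode needs a chain longer than the minimum separation"
        )

    pairs: list[tuple[str, int, str, int]] = []
    dists: list[float] = []
    sigmas: list[float] = []
    classes: list[str] = []

    if spec.mode in ("monomer", "dimer"):
        for chain in native.chains:
            X = chain.ca_coords
            n = len(chain)
            for i in range(n):
                for j in range(i + spec.min_separation, n):
                    pairs.append((chain.chain_id, i, chain.chain_id, j))
                    dists.append(float(np.linalg.norm(X[i] - X[j])))
                    sigmas.append(spec.sigma_base * (1 + (j - i)) ** spec.sigma_exponent)
                    classes.append("intra")

    if spec.mode in ("dimer", "interface"):
        sigma_inter = spec.sigma_base * (1 + spec.min_separation) ** spec.sigma_exponent
        for a_idx in range(len(native.chains)):
            for b_idx in range(a_idx + 1, len(native.chains)):
                ca, cb = native.chains[a_idx], native.chains[b_idx]
                D = np.linalg.norm(
                    ca.ca_coords[:, None, :] - cb.ca_coords[None, :, :], axis=2
                )
                for i in range(len(ca)):
                    for j in range(len(cb)):
                        d = float(D[i, j])
                        if spec.mode == "interface" and d > spec.interface_native_cutoff:
                            continue
                        pairs.append((ca.chain_id, i, cb.chain_id, j))
                        dists.append(d)
                        sigmas.append(sigma_inter)
                        classes.append("inter")

    if not pairs:
        raise ValueError(
            f"no pairs satisfy the {spec.mode!r} criteria "
            "(interface cutoff too small, or chains too short)"
        )
    return ContactReference(pairs, np.array(dists), np.array(sigmas), classes, spec)


def _pair_distances(conformation: Structure, reference: ContactReference,
                    pairing: dict[str, str] | None) -> np.ndarray:
    """Distances r_ij in the conformation for every reference pair."""
    chain_map = pairing or {cid: cid for cid in
                            {p[0] for p in reference.pairs} | {p[2] for p in reference.pairs}}
    coords: dict[str, np.ndarray] = {}
    missing: list[tuple[str, int]] = []
    for ref_cid in set(chain_map):
        conf_cid = chain_map[ref_cid]
        try:
            coords[ref_cid] = conformation.chain(conf_cid).ca_coords
        except KeyError:
            raise KeyError(
                f"conformation lacks chain {conf_cid!r} required by the pairing"
            ) from None
    for (ca, i, cb, j) in reference.pairs:
        if i >= len(coords[ca]):
            missing.append((ca, i))
        if j >= len(coords[cb]):
            missing.append((cb, j))
    if missing:
        raise IndexError(
            f"conformation does not cover reference residues: {sorted(set(missing))[:10]}"
            + ("..." if len(set(missing)) > 10 else "")
        )
    r = np.empty(len(reference))
    for k, (ca, i, cb, j) in enumerate(reference.pairs):
        r[k] = np.linalg.norm(coords[ca][i] - coords[cb][j])
    return r


def q_score(conformation: Structure, reference: ContactReference,
            pairing: dict[str, str] | None = None) -> float:
    """Q of a conformation against a prebuilt contact reference, in [0, 1].

    ``pairing`` maps reference chain ids to conformation chain ids (identity
    by default).  For homodimers, use :func:`q_score_best` to maximize over
    the ambiguous chain assignments.
    """
    r = _pair_distances(conformation, reference, pairing)
    terms = np.exp(-((r - reference.native_distance) ** 2)
                   / (2.0 * reference.sigma ** 2))
    return float(terms.mean())


def q_score_best(conformation: Structure, reference: ContactReference,
                 pairings: list[dict[str, str]]) -> tuple[float, dict[str, str]]:
    """Maximum Q over candidate chain pairings; returns (Q, best pairing)."""
    if not pairings:
        raise ValueError("no pairings supplied")
    scored = [(q_score(conformation, reference, p), p) for p in pairings]
    return max(scored, key=lambda t: t[0])


def _native_contact_pairs(native: Structure, contact_cutoff: float,
                          min_separation: int = 3):
    pairs = []
    chains = native.chains
    for c in chains:
        X = c.ca_coords
        for i in range(len(c)):
            for j in range(i + min_separation, len(c)):
                if np.linalg.norm(X[i] - X[j]) <= contact_cutoff:
                    pairs.append((c.chain_id, i, c.chain_id, j))
    for ai in range(len(chains)):
        for bi in range(ai + 1, len(chains)):
            ca, cb = chains[ai], chains[bi]
            D = np.linalg.norm(ca.ca_coords[:, None] - cb.ca_coords[None, :], axis=2)
            ii, jj = np.nonzero(D <= contact_cutoff)
            pairs.extend((ca.chain_id, int(i), cb.chain_id, int(j))
                         for i, j in zip(ii, jj))
    return pairs


def fraction_native_contacts(conformation: Structure, native: Structure,
                             contact_cutoff: float = 8.0,
                             tolerance_factor: float = 1.2,
                             pairing: dict[str, str] | None = None) -> float:
    """Fraction of native Cα contacts formed in a conformation.

    A native contact is a residue pair within ``contact_cutoff`` Å in the
    native structure (sequence separation ≥ 3 within a chain; all pairs
    across chains); it counts as formed when the conformation distance is
    ≤ ``tolerance_factor × contact_cutoff``.
    """
    if contact_cutoff <= 0 or tolerance_factor <= 0:
        raise ValueError("contact_cutoff and tolerance_factor must be > 0")
    pairs = _native_contact_pairs(native, contact_cutoff)
    if not pairs:
        raise ValueError(
            f"native structure has no contacts at cutoff {contact_cutoff} Å; "
            "fraction undefined"
        )
    ref = ContactReference(pairs, np.full(len(pairs), contact_cutoff),
                           np.ones(len(pairs)),
                           ["intra" if p[0] == p[2] else "inter" for p in pairs])
    r = _pair_distances(conformation, ref, pairing)
    formed = np.count_nonzero(r <= tolerance_factor * contact_cutoff)
    return formed / len(pairs)


def contact_map(native: Structure, contact_cutoff: float = 8.0) -> pd.DataFrame:
    """Native Cα contact list as a DataFrame edge list (for plotting)."""
    pairs = _native_contact_pairs(native, contact_cutoff)
    return pd.DataFrame(pairs, columns=["chain_a", "i", "chain_b", "j"])
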