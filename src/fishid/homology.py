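"""Panel-level COI homology analysis.

A :class:`COIPanel` holds barcodes for the target species and for the
congeneric control species (CONs) used as specificity negatives. From a
panel we compute an all-pairs identity matrix, rank CONs by homology to a
target (the closest-relative selection used when steering primer design
away from shared regions), and build a simple UPGMA tree on
``distance = 100 − percent identity``.

The tree is an ultrametric stand-in for a guide-tree cladogram: it answers
"which CON is closest" deterministically, and makes no further
phylogenetic claims.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seq import IUPACSequence, IUPAC_SETS, SequenceError, percent_identity


class PanelError(ValueError):
    """Raised for malformed panels or unknown species lookups."""


def consensus_sequence(seqs: list[IUPACSequence], name: str) -> IUPACSequence:
    """Majority-rule consensus of equal-length records; ties become the
    IUPAC code covering the tied bases.

    Pooling many barcode records per species into one consensus avoids
    intraspecies variation dominating pairwise identities.
    """
    if not seqs:
        raise PanelError(f"species {name!r} has no sequences")
    if len(seqs) == 1:
        return IUPACSequence(id=name, bases=seqs[0].bases)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise PanelError(
            f"species {name!r}: consensus requires equal-length records, got {sorted(lengths)}"
        )
    # reverse map from concrete-base sets to IUPAC codes
    set_to_code = {frozenset(v): k for k, v in IUPAC_SETS.items()}
    cols = []
    for i in range(lengths.pop()):
        counts = Counter(s.bases[i] for s in seqs)
        top = counts.most_common()
        best = top[0][1]
        tied = sorted(b for b, c in top if c == best)
        if len(tied) == 1:
            cols.append(tied[0])
        else:
            merged = frozenset().union(*(IUPAC_SETS[b] for b in tied))
            cols.append(set_to_code.get(merged, "N"))
    return IUPACSequence(id=name, bases="".join(cols))


@dataclass
class COIPanel:
    """Barcode panel split into target species and CON (control) species.

    ``con_species`` values are ``(sequences, in_great_lakes)`` pairs; the
    flag records whether the control co-occurs geographically with the
    targets and is used to filter closest-relative rankings.
    """

    target_species: dict[str, list[IUPACSequence]]
    con_species: dict[str, tuple[list[IUPACSequence], bool]]

    def __post_init__(self) -> None:
        dup = set(self.target_species) & set(self.con_species)
        if dup:
            raise PanelError(f"species present as both target and CON: {sorted(dup)}")
        for name, seqs in self.target_species.items():
            if not seqs:
                raise PanelError(f"target species {name!r} has no sequences")
        for name, (seqs, _) in self.con_species.items():
            if not seqs:
                raise PanelError(f"CON species {name!r} has no sequences")

    @property
    def species_names(self) -> list[str]:
        return list(self.target_species) + list(self.con_species)

    def representative(self, name: str, consensus: bool = True) -> IUPACSequence:
        """One sequence per species: majority consensus (default) or first record."""
        if name in self.target_species:
            seqs = self.target_species[name]
        elif name in self.con_species:
            seqs = self.con_species[name][0]
        else:
            raise PanelError(f"unknown species {name!r}")
        if consensus:
            return consensus_sequence(seqs, name)
        return IUPACSequence(id=name, bases=seqs[0].bases)

    def in_great_lakes(self, con_name: str) -> bool:
        try:
            return self.con_species[con_name][1]
        except KeyError:
            raise PanelError(f"unknown CON species {con_name!r}") from None


@dataclass
class IdentityMatrix:
    species_order: list[str]
    values: np.ndarray  # square, percent identity

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.species_order)
        if self.values.shape != (n, n):
            raise PanelError("identity matrix shape does not match species list")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise PanelError("identity matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 100.0):
            raise PanelError("identity matrix diagonal must be 100")
        if self.values.min() < 0 or self.values.max() > 100:
            raise PanelError("identities must lie in [0, 100]")

    def lookup(self, a: str, b: str) -> float:
        i = self.species_order.index(a)
        j = self.species_order.index(b)
        return float(self.values[i, j])

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.values, index=self.species_order, columns=self.species_order)
        df.to_csv(path, sep="\t", index_label="species")


@dataclass
class DistanceTree:
    newick: str
    leaf_names: list[str]


def identity_matrix(panel: COIPanel, consensus: bool = True) -> IdentityMatrix:
    """All-pairs integer percent identity over the panel's representatives."""
    names = panel.species_names
    if not names:
        raise PanelError("empty panel")
    reps = {n: panel.representative(n, consensus=consensus) for n in names}
    n = len(names)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            res = percent_identity(reps[names[i]], reps[names[j]])
            values[i, j] = values[j, i] = res.percent_identity
    return IdentityMatrix(species_order=names, values=values)


def closest_con(
    panel: COIPanel,
    target: str,
    restrict_to_great_lakes: bool = False,
    consensus: bool = True,
) -> list[tuple[str, int]]:
    """CON species ranked by descending percent identity to ``target``.

    Ties break lexicographically by CON name. With
    ``restrict_to_great_lakes`` only geographically co-occurring CONs are
    ranked (the filter never reorders survivors).
    """
    if target not in panel.target_species:
        raise PanelError(f"unknown target species {target!r}")
    rep = panel.representative(target, consensus=consensus)
    rows = []
    for con in sorted(panel.con_species):
        seqs, in_gl = panel.con_species[con]
        if restrict_to_great_lakes and not in_gl:
            continue
        res = percent_identity(rep, panel.representative(con, consensus=consensus))
        rows.append((con, res.percent_identity))
    rows.sort(key=lambda r: (-r[1], r[0]))
    return rows


def upgma_tree(matrix: IdentityMatrix) -> DistanceTree:
    """UPGMA tree on distance = 100 − identity, with lexicographic tie-breaks.

    At every step the pair at minimum distance is merged; equal-distance
    ties are resolved by the lexicographically smallest (name_a, name_b)
    pair, so the tree is deterministic for any input order. Branch lengths
    are ultrametric heights (distance / 2 at each merge).
    """
    names = list(matrix.species_order)
    if len(names) == 1:
        return DistanceTree(newick=f"{names[0]}:0.0;", leaf_names=names)
    dist: dict[frozenset, float] = {}
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            dist[frozenset((a, names[j]))] = 100.0 - matrix.values[i, j]

    # each live cluster: name -> (newick subtree, height, n_leaves, sort key)
    clusters: dict[str, tuple[str, float, int]] = {n: (n, 0.0, 1) for n in names}
    key_of = {n: n for n in names}  # lexicographic identity of a cluster

    while len(clusters) > 1:
        live = sorted(clusters, key=lambda c: key_of[c])
        best = None
        for i, a in enumerate(live):
            for b in live[i + 1 :]:
                d = dist[frozenset((a, b))]
                cand = (d, min(key_of[a], key_of[b]), max(key_of[a], key_of[b]))
                if best is None or cand < best[0]:
                    best = (cand, a, b)
        (d, _, _), a, b = best
        sub_a, h_a, n_a = clusters.pop(a)
        sub_b, h_b, n_b = clusters.pop(b)
        height = d / 2.0
        first, second = sorted(
            [(key_of[a], sub_a, h_a), (key_of[b], sub_b, h_b)], key=lambda t: t[0]
        )
        newick = (
            f"({first[1]}:{height - first[2]:.6g},{second[1]}:{height - second[2]:.6g})"
        )
        merged = f"__{a}+{b}__"
        clusters[merged] = (newick, height, n_a + n_b)
        key_of[merged] = min(key_of[a], key_of[b])
        for other in clusters:
            if other == merged:
                continue
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((merged, other))] = (da * n_a + db * n_b) / (n_a + n_b)
        dist.pop(frozenset((a, b)), None)

    (newick, height, _), = clusters.values()
    return DistanceTree(newick=newick + ";", leaf_names=names)
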