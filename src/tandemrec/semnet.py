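"""Undirected concept graph with inverse-distance term similarity.

Pairwise similarity between two concepts is derived from the unweighted
shortest-path distance d in the graph: identical concepts score 1, concepts
at distance d >= 1 score 1/(d+1), and pairs that are disconnected or farther
apart than ``d_max`` score 0.  This keeps similarity in [0, 1], makes
identity strictly dominate adjacency, and is monotone decreasing in d.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np

from .text import PorterStemmer, tokenize

__all__ = ["SemanticNetwork", "concept_similarity"]

logger = logging.getLogger(__name__)

DEFAULT_D_MAX = 4


class SemanticNetwork:
    """A set of concepts, undirected edges, and a surface-form index.

    The surface-form index maps word *stems* to concept identifiers so that
    stemmed description tokens can be resolved to graph nodes.
    """

    def __init__(
        self,
        concepts: "list[str] | set[str]",
        edges: "list[tuple[str, str]]" = (),
        surface_forms: "dict[str, list[str]] | None" = None,
    ) -> None:
        self.graph = nx.Graph()
        self.graph.add_nodes_from(concepts)
        for a, b in edges:
            if a not in self.graph or b not in self.graph:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown concept")
            self.graph.add_edge(a, b)
        stemmer = PorterStemmer()
        self.surface_index: dict[str, str] = {}
        for concept, forms in (surface_forms or {}).items():
            if concept not in self.graph:
                raise ValueError(f"surface forms given for unknown concept {concept!r}")
            for form in forms:
                stem = stemmer.stem(form.strip().lower())
                prev = self.surface_index.setdefault(stem, concept)
                if prev != concept:
                    logger.warning(
                        "surface form %r maps to both %r and %r; keeping %r",
                        form, prev, concept, prev,
                    )
        self._dist_cache: dict[int, dict[str, dict[str, int]]] = {}

    # -- basic container protocol ------------------------------------------

    @property
    def concepts(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, concept: str) -> bool:
        return concept in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    # -- resolution ---------------------------------------------------------

    def resolve(self, stem: str) -> str | None:
        """Concept for a word stem, or None if the stem is unindexed."""
        return self.surface_index.get(stem)

    def resolve_words(self, words: "list[str]") -> set[str]:
        """Resolve raw words (tokenised + stemmed here) to concepts.

        Unresolvable words are dropped with a warning so that all similarity
        arithmetic stays inside one graph.
        """
        stemmer = PorterStemmer()
        out: set[str] = set()
        for word in words:
            for token in tokenize(word):
                concept = self.resolve(stemmer.stem(token))
                if concept is None:
                    logger.warning("unresolved biography/term word: %r", word)
                else:
                    out.add(concept)
        return out

    # -- distances and similarity ------------------------------------------

    def _distances(self, d_max: int) -> dict[str, dict[str, int]]:
        """All-pairs shortest-path lengths up to ``d_max``, cached."""
        cached = self._dist_cache.get(d_max)
        if cached is None:
            cached = {
                src: dict(lengths)
                for src, lengths in nx.all_pairs_shortest_path_length(
                    self.graph, cutoff=d_max
                )
            }
            self._dist_cache[d_max] = cached
        return cached

    def similarity(self, a: str, b: str, d_max: int = DEFAULT_D_MAX) -> float:
        if a not in self.graph:
            raise KeyError(f"unknown concept: {a!r}")
        if b not in self.graph:
            raise KeyError(f"unknown concept: {b!r}")
        if a == b:
            return 1.0
        d = self._distances(d_max).get(a, {}).get(b)
        if d is None:  # disconnected or farther than d_max
            return 0.0
        return 1.0 / (d + 1)

    def similarity_matrix(
        self, concepts_a: "list[str]", concepts_b: "list[str]", d_max: int = DEFAULT_D_MAX
    ) -> np.ndarray:
        """Dense |A| x |B| pairwise similarity matrix (for fast soft Dice)."""
        dist = self._distances(d_max)
        out = np.zeros((len(concepts_a), len(concepts_b)))
        for i, a in enumerate(concepts_a):
            if a not in self.graph:
                raise KeyError(f"unknown concept: {a!r}")
            row = dist.get(a, {})
            for j, b in enumerate(concepts_b):
                if b not in self.graph:
                    raise KeyError(f"unknown concept: {b!r}")
                if a == b:
                    out[i, j] = 1.0
                else:
                    d = row.get(b)
                    if d is not None:
                        out[i, j] = 1.0 / (d + 1)
        return out

    # -- I/O ------------------------------------------------------------------

    @classmethod
    def load(cls, directory: str | Path) -> "SemanticNetwork":
        """Load from a directory holding ``concepts.tsv`` and ``edges.tsv``.

        ``concepts.tsv``: two tab-separated columns, concept id and a
        semicolon-separated list of surface forms (may be empty).
        ``edges.tsv``: two tab-separated concept ids per line.
        Lines starting with ``#`` are comments.
        """
        directory = Path(directory)
        concepts: list[str] = []
        surface: dict[str, list[str]] = {}
        for line in (directory / "concepts.tsv").read_text(encoding="utf-8").splitlines():
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            cid = parts[0].strip()
            concepts.append(cid)
            forms = [f for f in (parts[1].split(";") if len(parts) > 1 else []) if f.strip()]
            surface[cid] = forms or [cid]
        edges: list[tuple[str, str]] = []
        edges_path = directory / "edges.tsv"
        if edges_path.exists():
            for line in edges_path.read_text(encoding="utf-8").splitlines():
                if not line.strip() or line.startswith("#"):
                    continue
                a, b = line.split("\t")[:2]
                edges.append((a.strip(), b.strip()))
        return cls(concepts, edges, surface)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        inv: dict[str, list[str]] = {c: [] for c in self.graph.nodes}
        for stem, concept in self.surface_index.items():
            inv[concept].append(stem)
        lines = [f"{c}\t{';'.join(sorted(inv[c]))}" for c in sorted(self.graph.nodes)]
        (directory / "concepts.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
        edge_lines = [f"{a}\t{b}" for a, b in sorted(map(lambda e: tuple(sorted(e)), self.graph.edges))]
        (directory / "edges.tsv").write_text("\n".join(edge_lines) + ("\n" if edge_lines else ""), encoding="utf-8")


def concept_similarity(
    a: str, b: str, network: SemanticNetwork, d_max: int = DEFAULT_D_MAX
) -> float:
    """Inverse-shortest-distance similarity between two concepts.

    Returns 1 for identical concepts, 1/(d+1) for concepts at shortest-path
    distance d in [1, d_max], and 0 for disconnected or more distant pairs.
    Unknown concepts raise ``KeyError``.
    """
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    return network.similarity(a, b, d_max=d_max)
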