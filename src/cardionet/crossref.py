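"""Cross-platform intersection of differential signatures.

Two independently derived platform signatures are intersected into the
conserved concordant transcriptome: genes changed in the *same*
direction on both platforms. Genes changed in opposite directions are
reported as discordant, and genes differential on only one platform are
kept in per-platform-only sets rather than silently dropped, so the five
sets partition the union of the two signatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .exprfilter import Signature


@dataclass
class ConservedSignature:
    """Concordant intersection of two platform signatures.

    ``reduction_fraction`` is 1 - |conserved| / |smaller input signature|:
    the fraction of the more compact platform's candidate list removed by
    requiring cross-platform concordance.
    """

    conserved_up: frozenset[str]
    conserved_down: frozenset[str]
    discordant: frozenset[str]
    only_a: frozenset[str]
    only_b: frozenset[str]
    reduction_fraction: float
    provenance: dict = field(default_factory=dict)

    @property
    def conserved(self) -> frozenset[str]:
        return self.conserved_up | self.conserved_down


def intersect_signatures(sig_a: Signature, sig_b: Signature) -> ConservedSignature:
    """Intersect two signatures into the conserved concordant pool.

    Deterministic and order-independent: swapping the arguments swaps
    only the per-platform-only sets. When the two signatures' gene
    universes share no genes at all, the identifier namespaces probably
    differ; this is surfaced as a warning rather than an error.
    """
    if sig_a.universe and sig_b.universe and not (sig_a.universe & sig_b.universe):
        warnings.warn(
            "the two signatures share no genes at all; are the gene "
            "identifier namespaces compatible?",
            stacklevel=2,
        )
    genes_a = sig_a.up | sig_a.down
    genes_b = sig_b.up | sig_b.down
    conserved_up = sig_a.up & sig_b.up
    conserved_down = sig_a.down & sig_b.down
    discordant = (sig_a.up & sig_b.down) | (sig_a.down & sig_b.up)

    smaller = min(len(genes_a), len(genes_b))
    n_conserved = len(conserved_up) + len(conserved_down)
    reduction = 1.0 - n_conserved / smaller if smaller else 0.0

    return ConservedSignature(
        conserved_up=frozenset(conserved_up),
        conserved_down=frozenset(conserved_down),
        discordant=frozenset(discordant),
        only_a=frozenset(genes_a - genes_b),
        only_b=frozenset(genes_b - genes_a),
        reduction_fraction=reduction,
        provenance={"platform_a": sig_a.platform, "platform_b": sig_b.platform},
    )
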