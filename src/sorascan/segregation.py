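"""Perfect-segregation scanning of germline variants against responder status.

Alleles differing from the reference genome are coded "A" and reference-matching
alleles "B"; each genotype is the A-allele count g in {0,1,2}. A variant is 100%
associated with the good/poor split when its genotype vector satisfies one of
four inheritance subclasses:

==========  =========  ====================  ====================
 subclass    model      good responders       poor responders
==========  =========  ====================  ====================
 1           A-dom      g >= 1 (carrier)      g == 0
 2           A-rec      g == 2                g <= 1
 3           B-rec      g == 0                g >= 1
 4           B-dom      g <= 1                g == 2
==========  =========  ====================  ====================

Flipping every genotype g -> 2-g (swapping which allele is "A") exchanges
subclasses 1<->4 and 2<->3; this symmetry is asserted in the test suite.

Because the filter is an exact match rather than a statistical test, the module
also exposes the closed-form count of genotype vectors a monomorphic-free null
would match per subclass (:func:`null_match_count`), documenting the implied
family-wise false-positive expectation of the scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import (
    MISSING,
    GenotypeMatrix,
    SampleSheetRow,
    VariantSite,
    chrom_sort_key,
)

__all__ = [
    "ResponderLabels",
    "SubclassMatch",
    "classify_responders",
    "match_subclasses",
    "scan",
    "null_match_count",
    "DEFAULT_TTP_THRESHOLD",
]

#: Months of time-to-progression separating good from poor responders.
DEFAULT_TTP_THRESHOLD: float = 5.0

ResponderLabels = dict[str, str]  # sample ID -> "good" | "poor"


@dataclass
class SubclassMatch:
    site: VariantSite
    subclasses: frozenset[int]
    complete: bool  # no MISSING genotype at this site


def classify_responders(
    rows: Iterable[SampleSheetRow],
    ttp_threshold: float = DEFAULT_TTP_THRESHOLD,
) -> ResponderLabels:
    """Assign good/poor responder labels from explicit labels or TTP.

    An explicit label wins; otherwise a sample is a good responder iff its
    time-to-progression exceeds ``ttp_threshold`` months (default 5, the
    study's cutoff for poor responders). Raises if either class ends up empty,
    since the segregation scan is undefined without both.
    """
    if ttp_threshold <= 0:
        raise ValueError("ttp_threshold must be > 0")
    labels: ResponderLabels = {}
    for r in rows:
        if r.label is not None:
            labels[r.sample] = r.label
        else:
            labels[r.sample] = "good" if r.ttp_months > ttp_threshold else "poor"
    counts = {"good": 0, "poor": 0}
    for v in labels.values():
        counts[v] += 1
    for cls, n in counts.items():
        if n == 0:
            raise ValueError(f"responder class {cls!r} is empty; scan undefined")
    return labels


_RULES = {
    1: (lambda good, poor: bool((good >= 1).all() and (poor == 0).all())),
    2: (lambda good, poor: bool((good == 2).all() and (poor <= 1).all())),
    3: (lambda good, poor: bool((good == 0).all() and (poor >= 1).all())),
    4: (lambda good, poor: bool((good <= 1).all() and (poor == 2).all())),
}


def match_subclasses(
    g: Sequence[int] | np.ndarray,
    labels: Mapping[str, str],
    samples: Sequence[str],
    site: VariantSite | None = None,
    missing_policy: str = "exclude",
) -> SubclassMatch:
    """Evaluate the four segregation subclasses for one genotype vector.

    ``missing_policy="exclude"`` (default) reports no subclass when any
    genotype is MISSING; ``"tolerate"`` drops MISSING samples from the rule
    check. A responder class emptied of definite calls reports no subclass
    (perfect association is unverifiable on an empty class); the vector is
    flagged incomplete either way.
    """
    g = np.asarray(g, dtype=np.int8)
    if len(g) != len(samples):
        raise ValueError("genotype vector not aligned to samples")
    complete = bool((g != MISSING).all())
    if not complete and missing_policy == "exclude":
        return SubclassMatch(site, frozenset(), complete)
    keep = g != MISSING
    is_good = np.array([labels[s] == "good" for s in samples])
    good = g[keep & is_good]
    poor = g[keep & ~is_good]
    if good.size == 0 or poor.size == 0:
        return SubclassMatch(site, frozenset(), complete)
    matched = frozenset(k for k, rule in _RULES.items() if rule(good, poor))
    return SubclassMatch(site, matched, complete)


def scan(
    matrix: GenotypeMatrix,
    labels: Mapping[str, str],
    missing_policy: str = "exclude",
) -> list[SubclassMatch]:
    """Scan a genotype matrix for variants perfectly segregating with response.

    Returns one :class:`SubclassMatch` per variant whose genotype vector
    satisfies at least one subclass, ordered by (chrom, pos). Results are
    invariant to the order of samples and variant rows.
    """
    missing = set(matrix.samples) - set(labels)
    if missing:
        raise ValueError(f"samples without responder label: {sorted(missing)}")
    hits = []
    for i, site in enumerate(matrix.sites):
        m = match_subclasses(
            matrix.g[i], labels, matrix.samples, site, missing_policy
        )
        if m.subclasses:
            hits.append(m)
    hits.sort(key=lambda m: (chrom_sort_key(m.site.chrom), m.site.pos))
    return hits


def null_match_count(n_good: int, n_poor: int) -> dict:
    """Closed-form counts of complete genotype vectors matching each subclass.

    Over all 3^(n_good+n_poor) complete vectors: subclass 1 fixes the poor
    class at 0 and leaves {1,2} per good sample (2^n_good vectors); subclass 2
    fixes the good class at 2 and leaves {0,1} per poor sample (2^n_poor);
    subclasses 3 and 4 mirror them. The union applies inclusion–exclusion:
    the only non-empty intersections are 1∩2 (all good 2, all poor 0) and
    3∩4 (all good 0, all poor 2), one vector each.
    """
    if n_good < 1 or n_poor < 1:
        raise ValueError("n_good and n_poor must be >= 1")
    per = {
        1: 2 ** n_good,
        2: 2 ** n_poor,
        3: 2 ** n_poor,
        4: 2 ** n_good,
    }
    union = sum(per.values()) - 2  # subtract the 1∩2 and 3∩4 singletons
    return {**per, "union": union}
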