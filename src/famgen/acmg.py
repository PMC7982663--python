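"""ACMG/AMP five-tier variant classification: the evidence-combining algebra.

Evidence codes carry a category prefix — PVS (very strong pathogenic), PS
(strong), PM (moderate), PP (supporting), BA (stand-alone benign), BS (strong
benign), BP (supporting benign) — and :func:`combine_acmg` folds a set of
codes into one of five verdicts (pathogenic, likely pathogenic, uncertain
significance, likely benign, benign) following the published combining rules.
When both a pathogenic-side and a benign-side rule fire, the evidence is
contradictory and the verdict is uncertain significance, which is also the
default when no rule fires.
"""

from __future__ import annotations

import enum
import re
from collections import Counter
from dataclasses import dataclass

__all__ = ["AcmgCategory", "AcmgClassification", "AcmgEvidence", "combine_acmg"]

_CODE_RE = re.compile(r"^(PVS|PS|PM|PP|BA|BS|BP)(\d+)$")


class AcmgCategory(str, enum.Enum):
    PVS = "PVS"
    PS = "PS"
    PM = "PM"
    PP = "PP"
    BA = "BA"
    BS = "BS"
    BP = "BP"


class AcmgClassification(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    UNCERTAIN = "uncertain_significance"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"


@dataclass(frozen=True)
class AcmgEvidence:
    """A set of distinct evidence codes, e.g. {"PVS1", "PM2", "PP3"}."""

    codes: frozenset[str]

    def __init__(self, codes) -> None:
        codes = frozenset(codes)
        for code in codes:
            if not _CODE_RE.match(code):
                raise ValueError(f"malformed ACMG evidence code {code!r}")
        object.__setattr__(self, "codes", codes)

    def category_counts(self) -> Counter[AcmgCategory]:
        counts: Counter[AcmgCategory] = Counter()
        for code in self.codes:
            counts[AcmgCategory(_CODE_RE.match(code).group(1))] += 1
        return counts


def _pathogenic(pvs: int, ps: int, pm: int, pp: int) -> bool:
    if pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp >= 1) or pp >= 2):
        return True
    if ps >= 2:
        return True
    if ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)):
        return True
    return False


def _likely_pathogenic(pvs: int, ps: int, pm: int, pp: int) -> bool:
    if pvs >= 1 and pm == 1:
        return True
    if ps == 1 and 1 <= pm <= 2:
        return True
    if ps == 1 and pp >= 2:
        return True
    if pm >= 3:
        return True
    if pm == 2 and pp >= 2:
        return True
    if pm == 1 and pp >= 4:
        return True
    return False


def combine_acmg(evidence: AcmgEvidence) -> AcmgClassification:
    """Fold an evidence set into the five-tier verdict.

    Deterministic; conflicting pathogenic and benign rule hits resolve to
    uncertain significance, as does an empty or inconclusive set.
    """
    c = evidence.category_counts()
    pvs, ps, pm, pp = (c[AcmgCategory[k]] for k in ("PVS", "PS", "PM", "PP"))
    ba, bs, bp = (c[AcmgCategory[k]] for k in ("BA", "BS", "BP"))

    path_hit = _pathogenic(pvs, ps, pm, pp)
    lp_hit = _likely_pathogenic(pvs, ps, pm, pp)
    benign_hit = ba >= 1 or bs >= 2
    lb_hit = (bs >= 1 and bp >= 1) or bp >= 2

    if (path_hit or lp_hit) and (benign_hit or lb_hit):
        return AcmgClassification.UNCERTAIN
    if path_hit:
        return AcmgClassification.PATHOGENIC
    if lp_hit:
        return AcmgClassification.LIKELY_PATHOGENIC
    if benign_hit:
        return AcmgClassification.BENIGN
    if lb_hit:
        return AcmgClassification.LIKELY_BENIGN
    return AcmgClassification.UNCERTAIN
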