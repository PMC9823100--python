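"""ACMG/AMP variant classification: categorical rules and Bayesian odds.

Two parallel systems are implemented over the standard evidence codes
(PVS1, PS1-PS4, PM1-PM6, PP1-PP5 on the pathogenic side; BA1, BS1-BS4,
BP1-BP7 on the benign side):

* the published categorical combining rules, mapping counted evidence
  strengths to pathogenic / likely pathogenic / VUS / likely benign / benign;
* the Bayesian adaptation in which each strength carries an odds of
  pathogenicity (supporting 2.08, moderate 4.33, strong 18.7, very strong
  350), the per-code odds multiply, and the combined odds update a prior
  probability of pathogenicity (default 0.10) into a posterior that is
  thresholded into the same categories.

Benign evidence contributes reciprocal odds of the same strength.  The
rounded odds constants are the default; the exact exponential ladder
``350**(2**-k)`` is available via ``OddsModel(exact=True)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

STRENGTHS = ("supporting", "moderate", "strong", "very strong", "stand-alone")

# code -> (side, default strength)
CODE_TABLE: dict[str, tuple[str, str]] = {}
CODE_TABLE["PVS1"] = ("pathogenic", "very strong")
for _k in range(1, 5):
    CODE_TABLE[f"PS{_k}"] = ("pathogenic", "strong")
for _k in range(1, 7):
    CODE_TABLE[f"PM{_k}"] = ("pathogenic", "moderate")
for _k in range(1, 6):
    CODE_TABLE[f"PP{_k}"] = ("pathogenic", "supporting")
CODE_TABLE["BA1"] = ("benign", "stand-alone")
for _k in range(1, 5):
    CODE_TABLE[f"BS{_k}"] = ("benign", "strong")
for _k in range(1, 8):
    CODE_TABLE[f"BP{_k}"] = ("benign", "supporting")


class EvidenceError(ValueError):
    pass


@dataclass(frozen=True)
class EvidenceCode:
    """One applied criterion, optionally with a strength override."""

    code: str
    strength: str | None = None   # None -> the code's default strength
    justification: str = ""

    def __post_init__(self) -> None:
        if self.code not in CODE_TABLE:
            raise EvidenceError(f"unknown evidence code {self.code!r}")
        if self.strength is not None and self.strength not in STRENGTHS:
            raise EvidenceError(f"invalid strength {self.strength!r}")

    @property
    def side(self) -> str:
        return CODE_TABLE[self.code][0]

    @property
    def effective_strength(self) -> str:
        return self.strength or CODE_TABLE[self.code][1]


class EvidenceSet:
    """A set of evidence codes; duplicate code ids are rejected."""

    def __init__(self, codes) -> None:
        items = [c if isinstance(c, EvidenceCode) else EvidenceCode(c)
                 for c in codes]
        ids = [c.code for c in items]
        if len(set(ids)) != len(ids):
            raise EvidenceError(f"duplicate evidence codes in {ids}")
        self.codes = tuple(items)

    def __iter__(self):
        return iter(self.codes)

    def __len__(self) -> int:
        return len(self.codes)

    def counts(self, side: str) -> dict[str, int]:
        out = {s: 0 for s in STRENGTHS}
        for c in self.codes:
            if c.side == side:
                out[c.effective_strength] += 1
        return out

    @classmethod
    def from_yaml(cls, path) -> "EvidenceSet":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(payload["codes"])


# ---------------------------------------------------------------------------
# Categorical combining rules
# ---------------------------------------------------------------------------

def _pathogenic_tier(vs: int, s: int, m: int, p: int) -> str | None:
    """Evaluate the pathogenic-side combining table on strength counts."""
    pathogenic = (
        (vs >= 1 and (s >= 1 or m >= 2 or (m == 1 and p == 1) or p >= 2))
        or s >= 2
        or (s == 1 and (m >= 3 or (m == 2 and p >= 2) or (m == 1 and p >= 4)))
    )
    if pathogenic:
        return "pathogenic"
    likely = (
        (vs == 1 and m == 1)
        or (s == 1 and 1 <= m <= 2)
        or (s == 1 and p >= 2)
        or m >= 3
        or (m == 2 and p >= 2)
        or (m == 1 and p >= 4)
    )
    if likely:
        return "likely pathogenic"
    return None


def _benign_tier(stand_alone: int, bs: int, bp: int) -> str | None:
    if stand_alone >= 1 or bs >= 2:
        return "benign"
    if (bs == 1 and bp >= 1) or bp >= 2:
        return "likely benign"
    return None


def classify_rules(evidence: EvidenceSet) -> str:
    """Categorical ACMG/AMP class from the published combining rules.

    Simultaneously satisfied pathogenic and benign rules are contradictory
    evidence and yield VUS.
    """
    pc = evidence.counts("pathogenic")
    bc = evidence.counts("benign")
    path = _pathogenic_tier(pc["very strong"], pc["strong"], pc["moderate"],
                            pc["supporting"])
    ben = _benign_tier(bc["stand-alone"], bc["strong"], bc["supporting"])
    if path and ben:
        return "VUS"
    return path or ben or "VUS"


# ---------------------------------------------------------------------------
# Bayesian odds framework
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OddsModel:
    """Per-strength odds of pathogenicity and posterior thresholds.

    The rounded constants reproduce published worked examples; with
    ``exact=True`` the self-consistent exponential ladder
    ``odds(strength k) = 350**(2**-k)`` is used instead.
    """

    odds_very_strong: float = 350.0
    odds_strong: float = 18.7
    odds_moderate: float = 4.33
    odds_supporting: float = 2.08
    prior: float = 0.10
    threshold_pathogenic: float = 0.99
    threshold_likely_pathogenic: float = 0.90
    threshold_likely_benign: float = 0.10
    threshold_benign: float = 0.001
    exact: bool = False

    def odds_for(self, strength: str) -> float:
        if self.exact:
            ladder = {"very strong": 350.0 ** 1, "strong": 350.0 ** 0.5,
                      "moderate": 350.0 ** 0.25, "supporting": 350.0 ** 0.125,
                      "stand-alone": 350.0}
            return ladder[strength]
        table = {"very strong": self.odds_very_strong,
                 "strong": self.odds_strong,
                 "moderate": self.odds_moderate,
                 "supporting": self.odds_supporting,
                 # benign stand-alone carries very-strong weight
                 "stand-alone": self.odds_very_strong}
        return table[strength]

    def category(self, post: float) -> str:
        if post >= self.threshold_pathogenic:
            return "pathogenic"
        if post >= self.threshold_likely_pathogenic:
            return "likely pathogenic"
        if post < self.threshold_benign:
            return "benign"
        if post <= self.threshold_likely_benign:
            return "likely benign"
        return "VUS"


DEFAULT_ODDS = OddsModel()


def combined_odds(evidence: EvidenceSet, model: OddsModel = DEFAULT_ODDS) -> float:
    """Product of per-code odds; benign evidence contributes reciprocals."""
    odds = 1.0
    for code in evidence:
        factor = model.odds_for(code.effective_strength)
        odds *= factor if code.side == "pathogenic" else 1.0 / factor
    return odds


def posterior(odds: float, prior: float) -> float:
    """Posterior probability of pathogenicity from combined odds and prior."""
    if not 0 < prior < 1:
        raise ValueError(f"prior must be in (0, 1), got {prior}")
    if odds <= 0:
        raise ValueError(f"odds must be positive, got {odds}")
    return odds * prior / (odds * prior + 1 - prior)


@dataclass(frozen=True)
class ClassificationResult:
    rule_category: str
    odds: float
    posterior: float
    bayes_category: str

    @property
    def concordant(self) -> bool:
        return self.rule_category == self.bayes_category

    def as_dict(self) -> dict:
        return {
            "rule_category": self.rule_category,
            "combined_odds": self.odds,
            "posterior": self.posterior,
            "bayes_category": self.bayes_category,
            "concordant": self.concordant,
        }


def classify_full(evidence: EvidenceSet,
                  model: OddsModel = DEFAULT_ODDS) -> ClassificationResult:
    """Run both classification systems; disagreement is reported, not hidden."""
    import warnings

    rule_cat = classify_rules(evidence)
    odds = combined_odds(evidence, model)
    post = posterior(odds, model.prior)
    bayes_cat = model.category(post)
    result = ClassificationResult(rule_cat, odds, post, bayes_cat)
    if not result.concordant:
        warnings.warn(
            f"rule-based class {rule_cat!r} disagrees with Bayesian class "
            f"{bayes_cat!r} (odds={odds:.3g}, posterior={post:.4f})",
            stacklevel=2)
    return result


# evidence satisfied by the index missense variant in the worked example:
# two moderate (hotspot domain, absent from controls) and four supporting
# (segregation, missense constraint, in-silico consensus, specific phenotype)
P81S_EVIDENCE = ("PM1", "PM2", "PP1", "PP2", "PP3", "PP4")
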