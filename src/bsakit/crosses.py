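"""Mendelian cross predictions and the complementation allelic test.

Two rival models describe a pair of recessive mutations a1 (a point
mutation) and a2 (an insertion allele):

* **allelic** — a1 and a2 are alleles of the same gene; the compound
  heterozygote a1/a2 is mutant because it carries no functional copy.
* **two-gene** — a1 and a2 hit different (unlinked) genes; each mutation
  is complemented by the other locus's functional allele, so inter-mutant
  crosses give only green progeny.

Progeny distributions are enumerated over gametes with exact rational
arithmetic; goodness of fit uses the Pearson chi-square statistic with the
upper tail from the regularized incomplete gamma function.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product

from scipy.special import gammaincc

__all__ = [
    "AlleleModel",
    "CrossSpec",
    "ProgenyPrediction",
    "Chi2Result",
    "expected_progeny",
    "chi_square_gof",
    "classify_allelism",
    "AllelismResult",
    "SegregationTest",
    "SegregationTestResults",
]

GREEN = "green"
PALE = "pale-green"

_ALLELE_RE = re.compile(r"([A-Za-z])([0-9]*)")


@dataclass(frozen=True)
class AlleleModel:
    """Which gene each allele belongs to, and which alleles are functional.

    ``allelic=True`` puts A1/a1/A2/a2 on a single gene (functional A1, A2;
    nonfunctional a1, a2). ``allelic=False`` assigns index-1 alleles to
    gene 1 and index-2 alleles to gene 2, unlinked. The mutant phenotype
    requires both alleles at some gene to be nonfunctional (recessive).
    """

    allelic: bool

    @classmethod
    def same_gene(cls) -> "AlleleModel":
        return cls(allelic=True)

    @classmethod
    def two_gene(cls) -> "AlleleModel":
        return cls(allelic=False)

    @property
    def name(self) -> str:
        return "allelic" if self.allelic else "two-gene"

    def locus_of(self, allele: str) -> str:
        m = _ALLELE_RE.fullmatch(allele)
        if not m:
            raise ValueError(f"unparseable allele symbol {allele!r}")
        idx = m.group(2) or "1"
        if idx not in ("1", "2"):
            raise ValueError(f"allele {allele!r} has unknown gene index {idx}")
        return "gene" if self.allelic else f"gene{idx}"

    def is_functional(self, allele: str) -> bool:
        return allele[0].isupper()

    def loci(self) -> list[str]:
        return ["gene"] if self.allelic else ["gene1", "gene2"]


def _parse_genotype(text: str) -> list[str]:
    """Split a genotype token like ``A2a2`` or ``Aa`` into allele symbols."""
    alleles = [m.group(0) for m in _ALLELE_RE.finditer(text) if m.group(0)]
    if len(alleles) % 2 != 0 or not alleles:
        raise ValueError(f"genotype {text!r} must list pairs of alleles")
    return alleles


@dataclass(frozen=True)
class CrossSpec:
    """Two parents as per-locus allele pairs, plus optional lethality.

    ``lethal`` lists homozygous genotype classes removed before
    phenotyping, as allele symbols (e.g. ``("a2", "a2")`` for an
    albino-lethal insertion homozygote).
    """

    parent1: tuple[tuple[str, tuple[str, str]], ...]
    parent2: tuple[tuple[str, tuple[str, str]], ...]
    lethal: tuple[tuple[str, str], ...] = ()

    @classmethod
    def from_string(
        cls,
        text: str,
        model: AlleleModel,
        lethal: tuple[tuple[str, str], ...] = (),
    ) -> "CrossSpec":
        """Parse ``"A2a2 x a1a1"``.

        A parent's unmentioned loci (two-gene model) default to homozygous
        functional — e.g. the point mutant ``a1a1`` is wild type at gene 2.
        """
        parts = re.split(r"\s*[x×]\s*", text.strip())
        if len(parts) != 2:
            raise ValueError(f"cross {text!r} must be 'GENOTYPE x GENOTYPE'")
        parents = []
        for token in parts:
            alleles = _parse_genotype(token)
            by_locus: dict[str, list[str]] = {}
            for a in alleles:
                by_locus.setdefault(model.locus_of(a), []).append(a)
            for locus, al in by_locus.items():
                if len(al) != 2:
                    raise ValueError(
                        f"parent {token!r} must carry exactly two alleles at "
                        f"{locus} (got {al})"
                    )
            for locus in model.loci():
                if locus not in by_locus:
                    # unmentioned locus: homozygous functional
                    idx = locus[-1] if locus[-1].isdigit() else "1"
                    by_locus[locus] = [f"A{idx}", f"A{idx}"]
            parents.append(
                tuple(sorted((k, (v[0], v[1])) for k, v in by_locus.items()))
            )
        return cls(parents[0], parents[1], tuple(lethal))


def _gametes(
    parent: tuple[tuple[str, tuple[str, str]], ...]
) -> list[tuple[tuple[tuple[str, str], ...], Fraction]]:
    """Enumerate gametes as ((locus, allele), ...) with exact probabilities."""
    loci = [k for k, _ in parent]
    choices = [v for _, v in parent]
    out = []
    p = Fraction(1, 2 ** len(loci))
    for combo in product(*choices):
        out.append((tuple(zip(loci, combo)), p))
    return out


@dataclass(frozen=True)
class ProgenyPrediction:
    """Exact phenotype distribution and its reduced integer ratio."""

    probs: dict[str, Fraction]
    genotype_probs: dict[tuple, Fraction]

    @property
    def ratio(self) -> tuple[int, int]:
        """(green, pale-green) in lowest integer terms."""
        g, p = self.probs.get(GREEN, Fraction(0)), self.probs.get(
            PALE, Fraction(0)
        )
        if p == 0:
            return (1, 0)
        if g == 0:
            return (0, 1)
        r = g / p
        return (r.numerator, r.denominator)


def expected_progeny(
    cross: CrossSpec, model: AlleleModel
) -> ProgenyPrediction:
    """Exact progeny phenotype distribution for a cross under a model.

    All gamete combinations are enumerated with rational probabilities;
    the recessive phenotype rule is applied per gene; lethal genotype
    classes are removed and the distribution renormalised.
    """
    for parent in (cross.parent1, cross.parent2):
        for locus, pair in parent:
            for a in pair:
                if model.locus_of(a) != locus:
                    raise ValueError(
                        f"allele {a!r} does not belong to {locus} under the "
                        f"{model.name} model"
                    )
    geno: dict[tuple, Fraction] = {}
    for g1, p1 in _gametes(cross.parent1):
        for g2, p2 in _gametes(cross.parent2):
            d1, d2 = dict(g1), dict(g2)
            key = tuple(
                (locus, tuple(sorted((d1[locus], d2[locus]))))
                for locus in sorted(d1)
            )
            geno[key] = geno.get(key, Fraction(0)) + p1 * p2

    def _is_lethal(key) -> bool:
        pairs = {pair for _, pair in key}
        return any(tuple(sorted(l)) in pairs for l in cross.lethal)

    surviving = {k: v for k, v in geno.items() if not _is_lethal(k)}
    total = sum(surviving.values(), Fraction(0))
    if total == 0:
        raise ValueError("all progeny classes are lethal")
    surviving = {k: v / total for k, v in surviving.items()}

    probs = {GREEN: Fraction(0), PALE: Fraction(0)}
    for key, p in surviving.items():
        mutant = any(
            not model.is_functional(a1) and not model.is_functional(a2)
            for _, (a1, a2) in key
        )
        probs[PALE if mutant else GREEN] += p
    assert sum(probs.values()) == 1
    return ProgenyPrediction(probs=probs, genotype_probs=surviving)


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    pvalue: float


def chi_square_gof(
    observed: dict[str, int],
    expected: dict[str, Fraction | float],
    *,
    yates: bool = False,
) -> Chi2Result:
    """Pearson goodness-of-fit test of counts against class probabilities.

    statistic = sum (O-E)^2 / E with E = total x probability; df =
    classes - 1; p-value is the upper tail of the chi-square distribution
    via the regularized incomplete gamma function Q(df/2, x/2). The
    optional Yates correction subtracts 0.5 from each |O-E|.
    """
    classes = sorted(set(observed) | set(expected))
    total = sum(observed.get(c, 0) for c in classes)
    if total <= 0:
        raise ValueError("total observed count must be positive")
    if any(observed.get(c, 0) < 0 for c in classes):
        raise ValueError("negative observed count")
    psum = sum(float(expected.get(c, 0)) for c in classes)
    if not math.isclose(psum, 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError(f"expected probabilities sum to {psum}, not 1")
    stat = 0.0
    for c in classes:
        p = float(expected.get(c, 0))
        o = observed.get(c, 0)
        if p == 0:
            if o > 0:
                raise ValueError(
                    f"class {c!r} has zero expected probability but "
                    f"{o} observed"
                )
            continue
        e = total * p
        dev = abs(o - e)
        if yates:
            dev = max(dev - 0.5, 0.0)
        stat += dev * dev / e
    df = sum(1 for c in classes if float(expected.get(c, 0)) > 0) - 1
    pvalue = float(gammaincc(df / 2.0, stat / 2.0)) if df > 0 else 1.0
    return Chi2Result(statistic=stat, df=df, pvalue=pvalue)


@dataclass
class SegregationTestResults:
    prediction: ProgenyPrediction
    chi2: Chi2Result
    observed: dict[str, int]

    def summary(self) -> str:
        g, p = self.prediction.ratio
        probs = ", ".join(
            f"{k}: {v} ({float(v):.4g})" for k, v in self.prediction.probs.items()
        )
        return "\n".join(
            [
                "Segregation test",
                "================",
                f"expected distribution: {probs}",
                f"expected ratio (green:pale): {g}:{p}",
                f"observed: {self.observed}",
                f"chi2 = {self.chi2.statistic:.4f}, df = {self.chi2.df}, "
                f"p = {self.chi2.pvalue:.4g}",
            ]
        )


class SegregationTest:
    """Fit observed progeny counts against one cross's predicted ratio."""

    def __init__(
        self,
        observed: dict[str, int],
        cross: CrossSpec | str,
        model: AlleleModel,
        *,
        yates: bool = False,
    ) -> None:
        if isinstance(cross, str):
            cross = CrossSpec.from_string(cross, model)
        self.observed = observed
        self.cross = cross
        self.model = model
        self.yates = yates

    def fit(self) -> SegregationTestResults:
        pred = expected_progeny(self.cross, self.model)
        chi2 = chi_square_gof(self.observed, pred.probs, yates=self.yates)
        return SegregationTestResults(
            prediction=pred, chi2=chi2, observed=self.observed
        )


@dataclass
class AllelismResult:
    """Verdict of the complementation allelic test across crosses."""

    verdict: str  # "allelic" | "non-allelic" | "inconclusive"
    table: list[dict]

    def summary(self) -> str:
        lines = ["Complementation allelic test", "============================"]
        for row in self.table:
            lines.append(
                f"{row['cross']}: observed {row['observed']} | "
                f"allelic ratio {row['allelic_ratio']} "
                f"p={row['allelic_p']:.4g} | "
                f"two-gene ratio {row['two_gene_ratio']} "
                f"p={row['two_gene_p']:.4g}"
                + ("  [informative]" if row["informative"] else "")
            )
        lines.append(f"verdict: {self.verdict}")
        return "\n".join(lines)


def classify_allelism(
    crosses: list[tuple[str, dict[str, int]]],
    *,
    alpha: float = 0.05,
    lethal: tuple[tuple[str, str], ...] = (("a2", "a2"),),
) -> AllelismResult:
    """Decide between the allelic and two-gene models from observed counts.

    Each item of ``crosses`` is ``(cross string, observed phenotype
    counts)``. A cross is informative when the two models predict
    different phenotype distributions. A model explaining every cross
    (chi-square not rejected at ``alpha``) while its rival is rejected in
    at least one informative cross wins; anything else is inconclusive.
    An observed class the model gives probability zero rejects the model
    outright.
    """
    models = {
        "allelic": AlleleModel.same_gene(),
        "two-gene": AlleleModel.two_gene(),
    }
    table = []
    any_informative = False
    rejected = {name: False for name in models}
    rejected_informative = {name: False for name in models}
    for text, observed in crosses:
        preds, pvals = {}, {}
        for name, model in models.items():
            spec = CrossSpec.from_string(text, model, lethal=lethal)
            pred = expected_progeny(spec, model)
            preds[name] = pred
            try:
                pvals[name] = chi_square_gof(observed, pred.probs).pvalue
            except ValueError:
                pvals[name] = 0.0  # impossible class observed
        informative = (
            preds["allelic"].probs != preds["two-gene"].probs
        )
        any_informative = any_informative or informative
        for name in models:
            if pvals[name] < alpha:
                rejected[name] = True
                if informative:
                    rejected_informative[name] = True
        table.append(
            {
                "cross": text,
                "observed": observed,
                "informative": informative,
                "allelic_ratio": preds["allelic"].ratio,
                "allelic_p": pvals["allelic"],
                "two_gene_ratio": preds["two-gene"].ratio,
                "two_gene_p": pvals["two-gene"],
            }
        )
    if not any_informative:
        raise ValueError(
            "designs do not discriminate: no cross separates the models"
        )
    verdict = "inconclusive"
    if not rejected["allelic"] and rejected_informative["two-gene"]:
        verdict = "allelic"
    elif not rejected["two-gene"] and rejected_informative["allelic"]:
        verdict = "non-allelic"
    return AllelismResult(verdict=verdict, table=table)
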