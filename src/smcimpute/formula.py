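"""Model-formula grammar.

``outcome ~ 1 + wdev(x) + cmean(x) + z + wdev(x):z + x^2 + (1 + wdev(x) | cluster)``

* ``cmean(v)`` — manifest cluster mean of ``v``
* ``wdev(v)``  — within-cluster deviation ``v - cmean(v)``
* ``v^k``      — integer power, k >= 2
* ``a:b``      — product (interaction) of factors
* ``(terms | cluster)`` — cluster-varying (random) part; level-1 models only
* a bare ``1`` keeps the intercept (the default); ``0`` removes it

``render_formula(parse_formula(s, ...))`` is parse-stable.
"""

from __future__ import annotations

import re

from .data import ModelSpec, TermSpec

__all__ = ["parse_formula", "render_formula", "FormulaError"]


class FormulaError(ValueError):
    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


_NAME = r"[A-Za-z_][A-Za-z0-9_.]*"
_FACTOR_RE = re.compile(
    rf"^(?:(?P<fn>cmean|wdev)\((?P<arg>{_NAME})\)|(?P<var>{_NAME})(?:\^(?P<pow>\d+))?)$"
)


def _parse_factor(text: str, offset: int) -> tuple:
    m = _FACTOR_RE.match(text.strip())
    if m is None:
        raise FormulaError(f"cannot parse factor {text.strip()!r}", offset)
    if m.group("fn"):
        tr = "cluster_mean" if m.group("fn") == "cmean" else "within_deviation"
        return (m.group("arg"), tr)
    if m.group("pow"):
        k = int(m.group("pow"))
        if k < 2:
            raise FormulaError("power exponent must be >= 2", offset)
        return (m.group("var"), "power", k)
    return (m.group("var"), "identity")


def _parse_term(text: str, offset: int) -> TermSpec:
    factors = tuple(_parse_factor(p, offset) for p in text.split(":"))
    return TermSpec(factors)


def _split_plus(text: str) -> list[str]:
    # top-level split on '+' (parentheses only arise from cmean/wdev calls)
    parts, depth, cur = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "+" and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    parts.append("".join(cur))
    return parts


def _extract_random_part(rhs: str) -> tuple[str | None, str]:
    depth, start = 0, -1
    for i, ch in enumerate(rhs):
        if ch == "(":
            if depth == 0:
                start = i
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormulaError("unbalanced parentheses", i)
            if depth == 0:
                seg = rhs[start + 1:i]
                d2, bar = 0, -1
                for j, c2 in enumerate(seg):
                    if c2 == "(":
                        d2 += 1
                    elif c2 == ")":
                        d2 -= 1
                    elif c2 == "|" and d2 == 0:
                        bar = j
                if bar >= 0:
                    return seg, rhs[:start] + rhs[i + 1:]
    if depth != 0:
        raise FormulaError("unbalanced parentheses", len(rhs))
    return None, rhs


def parse_formula(text: str, level: int = 1, cluster_name: str = "cluster"
                  ) -> ModelSpec:
    """Parse a formula string into a :class:`ModelSpec`."""
    if "~" not in text:
        raise FormulaError("formula must contain '~'", text.find("~"))
    lhs, rhs = text.split("~", 1)
    outcome = lhs.strip()
    if not re.match(rf"^{_NAME}$", outcome):
        raise FormulaError(f"bad outcome name {outcome!r}", 0)

    # peel off the random part "(terms | cluster)" (nesting-aware: the
    # terms may themselves contain cmean()/wdev() parentheses)
    random_part, rhs = _extract_random_part(rhs)
    if random_part is not None:
        rhs = re.sub(r"\+\s*$", "", rhs.strip()).strip()
        rhs = re.sub(r"\+\s*\+", "+", rhs)

    intercept = True
    terms: list[TermSpec] = []
    pos = len(lhs) + 1
    for part in _split_plus(rhs):
        p = part.strip()
        if p == "":
            continue
        if p == "1":
            intercept = True
        elif p == "0":
            intercept = False
        else:
            terms.append(_parse_term(p, pos + text[pos:].find(part)))

    random_intercept = False
    random_terms: list[TermSpec] = []
    if random_part is not None:
        if level == 2:
            raise FormulaError("random part not allowed in a level-2 model")
        rterms, group = random_part.split("|")
        group = group.strip()
        if group != cluster_name:
            raise FormulaError(
                f"random part grouped by {group!r}, expected {cluster_name!r}")
        for part in _split_plus(rterms):
            p = part.strip()
            if p == "" or p == "0":
                continue
            if p == "1":
                random_intercept = True
            else:
                t = _parse_term(p, 0)
                if t not in terms:
                    raise FormulaError(
                        f"random term {p!r} has no matching fixed term")
                random_terms.append(t)

    return ModelSpec(outcome=outcome, level=level, terms=tuple(terms),
                     intercept=intercept, random_intercept=random_intercept,
                     random_terms=tuple(random_terms))


def render_formula(spec: ModelSpec, cluster_name: str = "cluster") -> str:
    parts = ["1"] if spec.intercept else ["0"]
    parts += [t.label() for t in spec.terms]
    rhs = " + ".join(parts)
    if spec.n_random:
        rparts = ["1"] if spec.random_intercept else ["0"]
        rparts += [t.label() for t in spec.random_terms]
        rhs += f" + ({' + '.join(rparts)} | {cluster_name})"
    return f"{spec.outcome} ~ {rhs}"
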