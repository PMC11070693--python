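"""Indirect information contributions.

For every pair with positive marginal regularized information I'(X;Y), the
contribution of the k-th collected contributor is the fraction

    IndC(Ak; XY | {Ai}_{k-1}) = I'(X;Y;Ak|{Ai}_{k-1}) / I'(X;Y)

and the contributions plus the residual fraction I'(X;Y|{Ai}_n)/I'(X;Y) sum
to one exactly (the contributor collection telescopes the rectified
residual).  Removed pairs have residual fraction zero, so their separating
set accounts for 100% of the pair's information.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class ContributionRow:
    pair: tuple[str, str]
    contributor: str
    rank: int
    fraction: float  # IndC as a fraction of I'(X;Y)


@dataclass
class ContributionTable:
    rows: list[ContributionRow] = field(default_factory=list)
    residual_fraction: dict[tuple[str, str], float] = field(default_factory=dict)
    independent: set = field(default_factory=set)

    def for_pair(self, pair):
        return [r for r in self.rows if r.pair == pair]

    def summary_column(self) -> dict[tuple[str, str], str]:
        """``contributor:percentage`` lists (integer percent at the output
        layer; full precision retained in ``rows``)."""
        out: dict[tuple[str, str], str] = {}
        for key in self.independent:
            out[key] = "independent"
        for r in self.rows:
            part = f"{r.contributor}:{round(100.0 * r.fraction)}%"
            out[r.pair] = out.get(r.pair, "")
            out[r.pair] += (";" if out[r.pair] else "") + part
        return out


def indirect_contributions(records) -> ContributionTable:
    """Contribution table over all pairs with a SepSetRecord (connected and
    disconnected alike)."""
    table = ContributionTable()
    for key in sorted(records):
        rec = records[key]
        if rec.info0 <= 0.0:
            table.independent.add(key)
            continue
        for k, (a, c) in enumerate(zip(rec.contributors, rec.contributions),
                                   start=1):
            table.rows.append(ContributionRow(key, a, k, c / rec.info0))
        table.residual_fraction[key] = rec.residual / rec.info0
    return table
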