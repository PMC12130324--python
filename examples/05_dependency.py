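"""Normalize CRISPR gene-effect scores and call dependencies.

Rescales each cell line so the median effect of non-essential controls is 0
and of essential controls is -1, then calls a line dependent on a gene when
its normalized score falls below -0.5.  The planted dependency gene is the
duplicated SE's target; its expression rises with dependency strength, which
the Spearman association detects (rho near -1: higher expression, deeper
dependency score).
"""

import tempfile
from pathlib import Path

import pandas as pd

from sescout import GeneratorConfig, generate_cohorts
from sescout.dependency import (
    call_dependent,
    expression_dependency_association,
    normalize_gene_effect,
    read_gene_effect,
)

with tempfile.TemporaryDirectory() as tmp:
    bundle, truth = generate_cohorts(GeneratorConfig(seed=1), Path(tmp) / "bundle")
    raw = read_gene_effect(bundle.gene_effect, bundle.essential, bundle.nonessential)
    norm = normalize_gene_effect(raw)

    m_n = norm.scores.loc[list(norm.nonessential)].median(axis=0)
    m_e = norm.scores.loc[list(norm.essential)].median(axis=0)
    print("control medians after normalization (per line):")
    print(pd.DataFrame({"non-essential": m_n, "essential": m_e}).to_string())

    calls = call_dependent(norm, cutoff=-0.5)
    dep_gene = truth.dependent_pairs[0][0]
    print(f"\ndependent lines for {dep_gene}: {list(calls.columns[calls.loc[dep_gene]])}")

    expr = pd.read_csv(bundle.expression, sep="\t", index_col=0)
    res = expression_dependency_association(
        expr.loc[dep_gene].to_numpy(), norm.scores.loc[dep_gene].to_numpy()
    )
    print(
        f"expression vs dependency: rho={res.rho:.3f}, p={res.p_value:.3g} "
        f"({res.method}, n={res.n})"
    )
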