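"""Score somatic duplication recurrence over SE footprints.

Counts, per cancer-type cohort, the donors carrying a duplication that
covers at least half of each SE, and flags SEs duplicated in two or more
donors.  In the synthetic cohort one shared SE is recurrently duplicated in
the GI cohort only, so exactly one (SE, cohort) row is flagged.
"""

import tempfile
from pathlib import Path

from sescout import GeneratorConfig, generate_cohorts, merge_cohort
from sescout.sv import read_donor_manifest, read_sv_table, recurrent_amplicon_ses

with tempfile.TemporaryDirectory() as tmp:
    bundle, truth = generate_cohorts(GeneratorConfig(seed=1), Path(tmp) / "bundle")
    catalog = merge_cohort(
        {"planted": [s.span for s in truth.ses]}, cohort_id="planted"
    )
    events = read_sv_table(bundle.sv)
    donors = read_donor_manifest(bundle.donors)

    table = recurrent_amplicon_ses(
        catalog, events, donors, sorted(set(donors.values())),
        min_cover=0.5, min_donors=2,
    )
    print(f"{len(events)} SV events, {len(donors)} donors")
    print(table.to_string(index=False))
    flagged = table[table["recurrent"]]
    print(
        f"\nrecurrently duplicated: {flagged['se_id'].tolist()} "
        f"in {flagged['cohort'].tolist()} "
        f"(planted: {truth.duplicated_se} in {truth.dup_cohort})"
    )
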