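"""Zygosity classification and karyotype-constrained allele-copy assignment.

From the called tables of 02: classifies every (sample, site) as
complete/partial inactivation (cell lines) or indeterminate (tissue),
computes the cohort-wide complete-vs-partial split over mutated
cell-line sites, and — using the per-tumour karyotype table as the M-FISH
stand-in — assigns allele frequencies at multi-allelic sites to integer
chromosome copies and reports the copy-number lower bound at editing time.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]

from ampliclone.calling import frames_to_tables
from ampliclone.cohorts import TUMOUR_PLOIDIES, _full_ploidy
from ampliclone.panel import load_panel
from ampliclone.zygosity import (
    assign_allele_copies,
    classify_site,
    cohort_zygosity_fractions,
    min_copies_at_editing,
)

KINDS = {"PancTi": "normal", "Tu7_Ti": "tumour_tissue"}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    panel = load_panel(args.results / "panel_sites.tsv",
                       args.results / "panel_amplicons.fasta")
    chrom = {s.site_id: s.chrom for s in panel}
    tables = frames_to_tables(
        pd.read_csv(args.results / "site_tables.tsv", sep="\t"),
        pd.read_csv(args.results / "indel_catalogue.tsv", sep="\t"),
    )

    # karyotype table (M-FISH stand-in) for the tumour samples
    karyo_rows = [
        {"sample_id": tum, "chrom": c, "copy_number": k}
        for tum, overrides in TUMOUR_PLOIDIES.items()
        for c, k in _full_ploidy(panel, overrides).items()
    ]
    karyo = pd.DataFrame(karyo_rows)
    karyo.to_csv(args.results / "karyotypes.tsv", sep="\t", index=False)
    ploidy = {(r.sample_id, r.chrom): r.copy_number for r in karyo.itertuples()}

    status_rows, statuses = [], []
    copy_rows = []
    for sample_id, site_tables in sorted(tables.items()):
        kind = KINDS.get(sample_id, "cell_line")
        for site_id, table in site_tables.items():
            st = classify_site(table, kind)
            status_rows.append({
                "sample_id": sample_id, "site_id": site_id,
                "status": st.status,
                "cumulative_mrf": round(st.cumulative_mrf, 4),
                "min_copies_at_editing": min_copies_at_editing(table),
            })
            if st.status in ("complete", "partial"):
                statuses.append(st)
            k = ploidy.get((sample_id, chrom[site_id]))
            if kind == "cell_line" and k and table.alleles:
                freqs = {"WT": table.wt_fraction}
                for i, (_a, _s, mrf) in enumerate(table.alleles):
                    freqs[f"A{i + 1}"] = mrf
                total = sum(freqs.values())
                freqs = {l: f / total for l, f in freqs.items()}
                res = assign_allele_copies(freqs, int(k))
                copy_rows.append({
                    "sample_id": sample_id, "site_id": site_id,
                    "copy_number": k,
                    "assignment": json.dumps(res.copies),
                    "residual": round(res.residual, 5),
                    "ambiguous": res.ambiguous, "feasible": res.feasible,
                })

    status = pd.DataFrame(status_rows)
    status.to_csv(args.results / "status_matrix.tsv", sep="\t", index=False)
    pd.DataFrame(copy_rows).to_csv(
        args.results / "allele_copy_assignments.tsv", sep="\t", index=False
    )

    complete, partial = cohort_zygosity_fractions(statuses)
    print(f"zygosity over {len(statuses)} mutated cell-line sites: "
          f"{complete:.0%} complete, {partial:.0%} partial inactivation")
    feasible = [r for r in copy_rows if r["feasible"]]
    print(f"allele-copy assignments at {len(copy_rows)} mutated sites "
          f"({sum(1 for r in feasible if not r['ambiguous'])} unambiguous)")
    multi = status[status["min_copies_at_editing"] > 2]
    print(f"{len(multi)} sites demand >2 chromosome copies at editing time "
          f"(early polyploidization)")
    with open(args.results / "zygosity_summary.json", "w") as fh:
        json.dump({
            "mutated_cell_line_sites": len(statuses),
            "complete_fraction": complete,
            "partial_fraction": partial,
        }, fh, indent=2)


if __name__ == "__main__":
    main()
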