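#!/usr/bin/env python
"""Repertoire homology between compartments.

Per-patient Jaccard / Morisita-Horn indices for lung-tumor and blood-tissue
pairs plus top-100 prevalent-clone sharing; the planted structure should
show lung-tumor homology well above blood-tissue homology (paired Wilcoxon).
Also tabulates public clones (CDR3s seen in multiple patients). Writes
results/overlap.csv and results/public_clones.csv.
"""

from _common import ROOT, load_samples
from scipy.stats import wilcoxon

from tcrrep import overlap, pipeline


def main() -> None:
    _, samples = load_samples()
    table = pipeline.overlap_table(samples)
    out = ROOT / "results" / "overlap.csv"
    out.parent.mkdir(exist_ok=True)
    table.to_csv(out, index=False, lineterminator="\n")

    wide = table.pivot_table(
        index="patient_id", columns=["compartment_a", "compartment_b"], values="jaccard"
    )
    lt = wide[("ADJACENT_LUNG", "TUMOR")].dropna()
    pt = wide[("PBMC", "TUMOR")].dropna()
    stat = wilcoxon(lt, pt)
    print(f"median Jaccard lung-tumor {lt.median():.4f} vs blood-tumor {pt.median():.4f} "
          f"(Wilcoxon matched-pairs p = {stat.pvalue:.2e}, n = {len(lt)})")
    lt_rows = table[(table["compartment_a"] == "ADJACENT_LUNG") & (table["compartment_b"] == "TUMOR")]
    print("top-100 tumor clones detected in paired lung, median:",
          int(lt_rows["top100_detected_in_partner"].median()),
          "| also in lung top-100:", int(lt_rows["top100_in_partner_top100"].median()))

    nsclc = [s for s in samples if s.patient_id.startswith("P")]
    public = overlap.public_clones([s.productive_only() for s in nsclc], min_patients=2)
    public.to_csv(ROOT / "results" / "public_clones.csv", index=False, lineterminator="\n")
    print(f"public CDR3s (>= 2 patients): {len(public)}; wrote {out}")


if __name__ == "__main__":
    main()
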