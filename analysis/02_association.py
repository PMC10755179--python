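#!/usr/bin/env python
"""Clone-screen association between receptor-gene variants and the loss
of fruiting body formation.

Pools the published region-level clone-screen counts and tests each
region's 2x2 table (carrier x fruiting) with a two-sided Fisher's exact
test. Writes results/association.tsv.

Finding: variants in the 5' half of the gene (signal peptide +
extracellular binding domain) are strongly associated with non-fruiting
(88.7% of non-fruiters carry one vs 3.7% of fruiters; p << 1e-4);
variants in the 3' half (7-transmembrane domain) are not (94.9% vs
87.2%; p > 0.05).
"""

from pathlib import Path

import pandas as pd

from dictyvar.association import fisher_exact, odds_ratio
from dictyvar.tables import data_path, load_region_counts

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    regions = load_region_counts(data_path("clone_screen_regions.tsv"))
    rows = []
    for region, t in sorted(regions.items()):
        p = fisher_exact(t)
        orr = odds_ratio(t)
        rows.append({
            "region": region,
            "carriers_nonfruiting": t.a, "noncarriers_nonfruiting": t.b,
            "carriers_fruiting": t.c, "noncarriers_fruiting": t.d,
            "carrier_pct_nonfruiting": round(t.carrier_pct_nonfruiting(), 1),
            "carrier_pct_fruiting": round(t.carrier_pct_fruiting(), 1),
            "fisher_p": p,
            "odds_ratio": "inf" if orr.infinite else round(orr.value, 2),
        })
        print(f"{region}: table {t.cells}, "
              f"carriers among non-fruiters {t.carrier_pct_nonfruiting():.1f}%, "
              f"among fruiters {t.carrier_pct_fruiting():.1f}%, "
              f"Fisher p = {p:.3g}")

    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "association.tsv", sep="\t", index=False)
    print(f"wrote {OUT / 'association.tsv'}")


if __name__ == "__main__":
    main()
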