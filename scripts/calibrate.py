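"""Check the synthetic generator's calibration contract.

Generates SR and AF segments with the packaged defaults and verifies the
qualitative feature structure the analysis relies on:

* SR pRR30 / pRR3.25% concentrated near 0; AF values high;
* median H and HNR lower in AF, median HAR and HDR higher in AF;
* univariate AUC(pRR3.25%) >= 0.95 and >= AUC(H).

Run after any change to ``afhrv/generator_defaults.yaml`` (and bump its
``version``).  Usage::

    python scripts/calibrate.py [--seed 20240296] [--n 150]
"""

import argparse

from afhrv.classification import roc_auc
from afhrv.synthetic import DatasetSpec, gen_labelled_dataset

FEATURES = ["pRR30", "pRR3.25", "H", "HAR", "HDR", "HNR"]


def main() -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=20240296)
    ap.add_argument("--n", type=int, default=150, help="segments per class")
    args = ap.parse_args()

    _, table = gen_labelled_dataset(DatasetSpec(n_sr=args.n, n_af=args.n,
                                                seed=args.seed))
    med = table.groupby("class_label")[FEATURES].median()
    print(med.round(4))
    auc = {f: roc_auc(table[f], table["class_label"]).auc for f in FEATURES}
    print({k: round(v, 4) for k, v in auc.items()})

    checks = {
        "SR pRR30 near 0 (median < 10%)": med.loc["SR", "pRR30"] < 10,
        "AF pRR30 high (median > 60%)": med.loc["AF", "pRR30"] > 60,
        "AF pRR3.25% high (median > 70%)": med.loc["AF", "pRR3.25"] > 70,
        "median H lower in AF": med.loc["AF", "H"] < med.loc["SR", "H"],
        "median HNR lower in AF": med.loc["AF", "HNR"] < med.loc["SR", "HNR"],
        "median HAR higher in AF": med.loc["AF", "HAR"] > med.loc["SR", "HAR"],
        "median HDR higher in AF": med.loc["AF", "HDR"] > med.loc["SR", "HDR"],
        "AUC(pRR3.25%) >= 0.95": auc["pRR3.25"] >= 0.95,
        "AUC(pRR3.25%) >= AUC(H)": auc["pRR3.25"] >= auc["H"],
    }
    ok = True
    for name, passed in checks.items():
        print(("PASS" if passed else "FAIL"), name)
        ok &= passed
    return 0 if ok else 1


if __name__ == "__main__":
    raise SystemExit(main())
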