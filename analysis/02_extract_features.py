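#!/usr/bin/env python
"""Extract the radiomic panel from synthetic lesion phantoms.

Builds a small grid of phantoms varying the two generator dials that map
onto the planted signature — lobulation (shape irregularity, drives
compacity down) and intensity correlation length (texture smoothness,
drives GLCM homogeneity up) — extracts all 36 features on the native
anisotropic CT-like grid (0.8 x 0.8 x 3 mm), and writes the feature table.
"""

import os

import pandas as pd

from ctradiomics.features import extract_all
from ctradiomics.synthetic import PhantomSpec, generate_lesion

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    rows = []
    for lob in (0.0, 0.2, 0.4):
        for cl in (0.0, 1.5, 3.0):
            for seed in range(3):
                spec = PhantomSpec(
                    shape_family="lobulated" if lob > 0 else "ellipsoid",
                    lobulation=lob,
                    correlation_length=cl,
                    seed=seed,
                )
                vol, mask = generate_lesion(spec)
                fv = extract_all(vol, mask)
                rows.append({"lobulation": lob, "corr_length": cl, "seed": seed, **fv.values})
    df = pd.DataFrame(rows)
    df.to_csv(os.path.join(OUT, "phantom_features.csv"), index=False)

    by_lob = df.groupby("lobulation")[["sphericity", "compacity"]].mean()
    by_cl = df.groupby("corr_length")[["glcm_homogeneity", "glcm_contrast"]].mean()
    print("shape response to lobulation (mean over phantoms):")
    print(by_lob.round(4).to_string())
    print("\ntexture response to intensity correlation length:")
    print(by_cl.round(4).to_string())
    print(f"\nwrote {len(df)} phantom feature rows to results/phantom_features.csv")


if __name__ == "__main__":
    main()
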