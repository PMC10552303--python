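"""Tiny constructors shared across test modules."""
import numpy as np
import pandas as pd


def toy_matrix(values, kind="counts", features=None, samples=None):
    from litterlink.io import OmicsMatrix

    values = np.asarray(values)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return OmicsMatrix(pd.DataFrame(values, index=features, columns=samples), kind)


def toy_metadata(sample_ids, dam_ids, groups, sexes=None, tissue="intestine",
                 assay="transcriptome"):
    sexes = sexes or ["F"] * len(sample_ids)
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "dam_id": dam_ids,
            "group": groups,
            "sex": sexes,
            "tissue": tissue,
            "assay": assay,
        }
    )
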