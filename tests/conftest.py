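import numpy as np
import pandas as pd

from cpgprofiler.data_io import MethylationMatrix, cpg_label


def make_matrix(values, samples=None, n_replicates=1, labels=None) -> MethylationMatrix:
    """Build a MethylationMatrix from a (samples × CpGs) array, replicating
    each row ``n_replicates`` times."""
    values = np.asarray(values, dtype=float)
    n_s, n_c = values.shape
    samples = samples or [f"s{i + 1}" for i in range(n_s)]
    labels = labels or [cpg_label(j) for j in range(n_c)]
    rows, index = [], []
    for i, s in enumerate(samples):
        for r in range(1, n_replicates + 1):
            rows.append(values[i])
            index.append((s, r))
    data = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["sample", "replicate"]), columns=labels
    )
    return MethylationMatrix(data=data)
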