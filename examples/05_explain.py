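"""Attribute predictions to features, globally and for one sequence.

Global: exact Shapley attributions from the tree ensemble (margin
scale), ranked by mean |attribution|.  Local: a surrogate explanation
for the most confidently called positive, with the value range over
which each feature weight applies.
"""

from ac4cboost import (
    EncodingScheme,
    ModelConfig,
    SyntheticSpec,
    encode_dataset,
    generate_dataset,
    global_attribution,
    local_explanation,
    predict_proba,
    train,
)

seqs, y = generate_dataset(SyntheticSpec())
X = encode_dataset(seqs, EncodingScheme.EIIP_PSEEIIP)
model = train(X, y, ModelConfig())

report = global_attribution(model, X, top_k=10)
print("top 10 features by mean |Shapley attribution| (log-odds):")
for f in report.top_features:
    print(f"  {f['feature']:>10}  {f['mean_abs_attribution']:.4f}  "
          f"value-corr {f['value_attribution_corr']:+.2f}")
# Positive value-corr: high feature values push toward the ac4C call.

import numpy as np

idx = int(np.argmax(predict_proba(model, X)))
exp = local_explanation(model, X.values[idx], num_features=5, seed=42,
                        background=X, sequence_id=seqs[idx].id)
print(f"\nlocal explanation for {exp.sequence_id} "
      f"(P(ac4C) = {exp.predicted_probability:.3f}):")
for name, weight, active_range in exp.feature_weights:
    print(f"  {weight:+.4f}  {active_range}")
# Positive weights support the ac4C call, negative weights oppose it.
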