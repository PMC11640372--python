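"""Train the IDH/normal MLP on a synthetic cohort and report the four metrics.

Uses a 530+420 cohort, a stratified 70/15/15 split, and the default network
(16 inputs, 16 units per hidden layer, 2 softmax outputs) trained for 20
full-batch scaled-conjugate-gradient epochs on the cross-entropy loss.
Reports ACC/TPR/PPV (percent) and MCC on the held-out test split for 2-5
hidden layers.
"""

from dialysentinel import MLPConfig, evaluate, extract_features, generate_cohort, train

cases = generate_cohort(530, 420, master_seed=3)
features = [extract_features(c.series)[0] for c in cases]
print(f"{len(features)} labeled feature vectors")

print(f"\n{'layers':>6} {'ACC %':>7} {'TPR %':>7} {'PPV %':>7} {'MCC':>7}")
for layers in (2, 3, 4, 5):
    model = train(features, MLPConfig(n_hidden_layers=layers, seed=3))
    rep = evaluate(model, [features[i] for i in model.test_idx])
    print(f"{layers:>6} {rep.acc:>7.1f} {rep.tpr:>7.1f} {rep.ppv:>7.1f} {rep.mcc:>7.3f}")
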