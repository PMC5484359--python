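# Reduced-scale experiment grid: both representations, all five learners,
# all five oversampling rates, 25 repeats of z=10 synthetic-free pooled CV.
# Raise `repeats` to 100 for the full-budget simulation.
seed: 1
output_dir: results/experiment
representations: [profile, spectra]
learners: [adaboost-nb, adaboost-svm, adaboost-ann, adaboost-lda, random-forest]
rates: [0, 0.5, 1.0, 1.5, 2.0]
folds: 10
repeats: 25
minority_class: ependymoma
smote_k: 5
max_rounds: {profile: 100, spectra: 200}
pca_variance: 0.95
tune_forest: true
normalize_spectra: false
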