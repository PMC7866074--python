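{
  "mlr": {},
  "knn": {"n_neighbors": [1, 2, 3, 5, 7, 10, 15]},
  "dtree": {"max_depth": [2, 3, 4, 6, 8, null], "min_samples_leaf": [1, 3, 5]},
  "rforest": {
    "n_estimators": [100, 300],
    "max_depth": [4, 8, null],
    "max_features": [null, "sqrt"]
  },
  "gboost": {
    "n_estimators": [100, 300, 500],
    "learning_rate": [0.05, 0.1, 0.2],
    "max_depth": [2, 3, 4]
  }
}
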