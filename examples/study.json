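{
  "model": "rayleigh",
  "lam_true": 0.125,
  "x0": 2.5,
  "cells": [[10, 30], [10, 35], [15, 40], [20, 40]],
  "schemes": ["R1", "R2", "R3"],
  "methods": ["PP", "BP-J", "BP-U"],
  "uniform_bound": 3.0,
  "reps": 10000,
  "seed": 0
}
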