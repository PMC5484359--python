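# Per-class metabolite concentration means and standard deviations (mM-like
# arbitrary units on the spectral-fitting quantitation scale) for the three pediatric
# posterior-fossa tumor types, together with the cohort class sizes.  These
# parameterize the synthetic-cohort generator: within a class each variable
# is drawn from an independent normal with the listed mean/SD, clipped at 0.
# The 17 variables are the 14 classification metabolites plus the three
# grouped lipid/macromolecule resonances (TLM at 0.9 / 1.3 / 2.0 ppm).
classes:
  pilocytic_astrocytoma:
    n: 42
    metabolites:
      citrate:               {mean: 0.30, sd: 0.30}
      glycerophosphocholine: {mean: 0.77, sd: 0.50}
      glucose:               {mean: 2.61, sd: 1.83}
      glutamine:             {mean: 3.20, sd: 2.05}
      glutathione:           {mean: 0.19, sd: 0.38}
      glutamate:             {mean: 2.03, sd: 1.12}
      glycine:               {mean: 0.29, sd: 0.60}
      myo_inositol:          {mean: 1.23, sd: 1.92}
      lactate:               {mean: 1.98, sd: 1.05}
      phosphocholine:        {mean: 0.34, sd: 0.33}
      scyllo_inositol:       {mean: 0.03, sd: 0.12}
      taurine:               {mean: 0.66, sd: 0.68}
      total_creatine:        {mean: 1.22, sd: 1.29}
      total_naa:             {mean: 1.50, sd: 0.89}
      TLM09:                 {mean: 3.91, sd: 1.83}
      TLM13:                 {mean: 7.24, sd: 5.0}
      TLM20:                 {mean: 5.0,  sd: 2.21}
  medulloblastoma:
    n: 38
    metabolites:
      citrate:               {mean: 0.51, sd: 0.36}
      glycerophosphocholine: {mean: 2.22, sd: 1.16}
      glucose:               {mean: 1.6,  sd: 1.85}
      glutamine:             {mean: 2.34, sd: 1.97}
      glutathione:           {mean: 0.54, sd: 0.54}
      glutamate:             {mean: 3.73, sd: 2.73}
      glycine:               {mean: 3.21, sd: 2.50}
      myo_inositol:          {mean: 1.37, sd: 3.52}
      lactate:               {mean: 2.30, sd: 1.6}
      phosphocholine:        {mean: 1.14, sd: 0.79}
      scyllo_inositol:       {mean: 0.32, sd: 0.38}
      taurine:               {mean: 3.46, sd: 2.50}
      total_creatine:        {mean: 3.18, sd: 1.85}
      total_naa:             {mean: 1.11, sd: 0.77}
      TLM09:                 {mean: 6.90, sd: 4.12}
      TLM13:                 {mean: 19.88, sd: 14.2}
      TLM20:                 {mean: 9.40, sd: 3.89}
  ependymoma:
    n: 10
    metabolites:
      citrate:               {mean: 0.85, sd: 0.48}
      glycerophosphocholine: {mean: 1.56, sd: 0.89}
      glucose:               {mean: 2.04, sd: 1.23}
      glutamine:             {mean: 2.80, sd: 1.69}
      glutathione:           {mean: 0.60, sd: 0.71}
      glutamate:             {mean: 3.94, sd: 1.87}
      glycine:               {mean: 2.60, sd: 4.20}
      myo_inositol:          {mean: 6.19, sd: 4.78}
      lactate:               {mean: 2.16, sd: 1.64}
      phosphocholine:        {mean: 0.47, sd: 0.40}
      scyllo_inositol:       {mean: 0.21, sd: 0.30}
      taurine:               {mean: 1.58, sd: 1.49}
      total_creatine:        {mean: 4.17, sd: 1.89}
      total_naa:             {mean: 0.94, sd: 0.49}
      TLM09:                 {mean: 6.11, sd: 2.27}
      TLM13:                 {mean: 20.85, sd: 16.4}
      TLM20:                 {mean: 8.04, sd: 3.85}
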