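# Packaged coefficient registry: published GPDD-wide resampling-median
# logistic coefficients per pest group, so prediction works out of the box
# without access to the restricted database. A registry fitted on user data
# overrides this file.
#
# Model M1: logit(S) = b0 + b1 * log10(PD + 1)
# Model M2: logit(S) = b0 + b1 * log10(PD + 1) + b2 * n_known
# Values are resampling medians with 95% quantile confidence intervals.
provenance: paper-table
groups:
  bacteria:
    n_pests: 30
    M1:
      b0: {median: 3.2613, ci: [1.5581, 4.3791]}
      b1: {median: -2.9706, ci: [-3.4605, -2.2215]}
      slope_significant: true
    M2:
      b0: {median: 3.7354, ci: [1.7502, 5.2889]}
      b1: {median: -3.5794, ci: [-4.2790, -2.7080]}
      b2: {median: 0.0664, ci: [0.0634, 0.0711]}
  fungi:
    n_pests: 95
    M1:
      b0: {median: 4.3961, ci: [3.1958, 5.3539]}
      b1: {median: -3.3249, ci: [-3.7439, -2.8019]}
      slope_significant: true
    M2:
      b0: {median: 6.0593, ci: [5.0467, 6.7900]}
      b1: {median: -4.5293, ci: [-4.8649, -4.0673]}
      b2: {median: 0.0466, ci: [0.0455, 0.0483]}
  oomycetes:
    n_pests: 32
    M1:
      b0: {median: 2.0763, ci: [-0.8020, 3.6867]}
      b1: {median: -2.6679, ci: [-3.3745, -1.4216]}
      slope_significant: true
    M2:
      b0: {median: 3.2131, ci: [0.3439, 4.9863]}
      b1: {median: -3.5290, ci: [-4.3281, -2.2792]}
      b2: {median: 0.0818, ci: [0.0788, 0.0918]}
  insects:
    n_pests: 637
    M1:
      b0: {median: 3.2441, ci: [2.7108, 3.7216]}
      b1: {median: -2.7004, ci: [-2.9073, -2.4694]}
      slope_significant: true
    M2:
      b0: {median: 3.4837, ci: [2.9285, 3.9645]}
      b1: {median: -3.2188, ci: [-3.4273, -2.9736]}
      b2: {median: 0.0532, ci: [0.0526, 0.0539]}
  mites:
    n_pests: 87
    M1:
      b0: {median: 1.9584, ci: [0.3266, 2.9620]}
      b1: {median: -2.1681, ci: [-2.6039, -1.4625]}
      slope_significant: true
    M2:
      b0: {median: 2.6463, ci: [1.1852, 3.6436]}
      b1: {median: -2.8747, ci: [-3.3190, -2.2357]}
      b2: {median: 0.0447, ci: [0.0438, 0.0462]}
  mollusks:
    n_pests: 37
    M1:
      b0: {median: -0.4667, ci: [-4.5587, 1.5261]}
      b1: {median: -1.1391, ci: [-1.9896, -0.5920]}
      # The published analysis calls the mollusk phylogenetic signal
      # non-significant; predictions for this group warn accordingly.
      slope_significant: false
    M2:
      b0: {median: -1.2019, ci: [-3.7591, 0.8348]}
      b1: {median: -1.1576, ci: [-2.0378, -0.0713]}
      b2: {median: 0.0474, ci: [0.0467, 0.0495]}
  nematodes:
    n_pests: 70
    M1:
      b0: {median: 2.7157, ci: [1.8376, 3.4603]}
      b1: {median: -2.6249, ci: [-2.9498, -2.2445]}
      slope_significant: true
    M2:
      b0: {median: 2.2984, ci: [1.3244, 3.1807]}
      b1: {median: -2.9162, ci: [-3.3146, -2.4921]}
      b2: {median: 0.0884, ci: [0.0857, 0.0932]}
  viruses:
    n_pests: 108
    M1:
      b0: {median: 8.4044, ci: [7.7856, 8.9129]}
      b1: {median: -5.2014, ci: [-5.4320, -4.9236]}
      slope_significant: true
    M2:
      b0: {median: 8.3535, ci: [7.5721, 9.0395]}
      b1: {median: -5.6544, ci: [-5.9872, -5.2985]}
      b2: {median: 0.0967, ci: [0.0904, 0.1029]}
  plants:
    n_pests: 53
    M1:
      b0: {median: 1.9979, ci: [1.0617, 2.5609]}
      b1: {median: -2.2775, ci: [-2.5233, -1.8644]}
      slope_significant: true
    M2:
      b0: {median: 2.2164, ci: [1.2404, 2.8660]}
      b1: {median: -2.7873, ci: [-3.0934, -2.3506]}
      b2: {median: 0.0727, ci: [0.0704, 0.0782]}

# Directly comparable equation from empirical cross-inoculation host-range
# testing of necrotrophic foliar fungi on tropical trees (Gilbert & Webb):
# logit(S) = 2.9113 - 1.5944 * log10(PD + 1)
empirical_fungi_gilbert_webb:
  b0: 2.9113
  b1: -1.5944

# Summary of the GPDD extract behind the packaged coefficients: 210 host
# genera, 1670 pests, 15328 recorded pest x genus associations. Pest counts
# per group feed the paper-scale synthetic fixture.
reference_dataset:
  n_genera: 210
  n_pests: 1670
  n_positive_cells: 15328
  pests_per_group:
    bacteria: 52
    fungi: 212
    oomycetes: 61
    insects: 870
    mites: 119
    mollusks: 45
    nematodes: 105
    viruses: 135
    plants: 71
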