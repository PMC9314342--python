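"""Central numeric tolerances for the whole suite (voxel units unless noted)."""

# Lie-algebra oracle suite (32^3 smooth fields)
LOG_EXP_ROUNDTRIP_REL = 0.02        # relative norm error of log(exp(v)) vs v
INV_CONSISTENCY_MAX = 0.1           # max interior |exp(v) o exp(-v)|
BCH2_WIN_FRACTION = 0.95            # order-2 beats order-1 vs direct composition
BCH_SEQUENCE_ENDPOINT_MEAN = 0.25   # mean interior endpoint error vs direct composition
CONSTANT_FLOW_MAX = 0.05            # translation flow interior error
COMPOSE_ASSOCIATIVITY_MAX = 0.05    # association-order discrepancy

# registration
AFFINE_IDENTITY_TOL = 1e-3          # identical images: matrix/offset deviation
AFFINE_TRANSLATION_TOL = 0.2        # voxels
AFFINE_LINEAR_REL = 0.02            # relative error of recovered linear part
SVF_SELF_NORM_FRACTION = 0.01       # ||v|| for moving == fixed, vs unit constant field
SVF_RECOVERY_EPE = 0.5              # mean endpoint error over phantom foreground
SVF_MSE_RATIO = 0.2                 # post/pre registration MSE
GROUPWISE_MEAN_FRACTION = 0.05      # mean SVF norm vs mean individual norm
GROUPWISE_SHUFFLE_MSE_REL = 0.01    # G change under input shuffling, vs image variance

# model builder
TRANSPORT_IDENTITY_REL = 0.02       # v_M = 0 round trip
TRANSPORT_ORACLE_ENDPOINT = 0.25    # mean endpoint error vs definitional composition
GAMMA_SYMMETRY_MAX = 0.1            # uniform-magnitude synthetic run
COMPOSED_WARP_MSE_FACTOR = 1.5      # composed vs chained pairwise warping

# model API / synthetic validation
GENERATED_SSIM_MIN = 0.90           # per-timepoint vs proxy ground truth
MAP_SUBJECT_SSIM_MIN = 0.98         # model-generated subject mapped back to G
CONTINUITY_MSE_REL = 0.01           # T(t+0.1yr) vs T(t), relative to image variance
ZERO_AGING_MSE_REL = 0.01           # zero-aging cohort: templates vs G
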