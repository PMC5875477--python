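"""Frozen elemental photon-interaction tables, 10-150 keV.

Mass attenuation totals for H, C, N, O, Al transcribed from standard
published compilations; minor tissue/bone elements reconstructed from a
photoelectric Z-E scaling anchored on Al/P/Ca plus the exact free-electron
Klein-Nishina incoherent term and a calibrated coherent fit. The split into
processes is total-preserving and approximate below ~20 keV (no incoherent
scattering-function correction). Units: cm^2/g, energies keV."""
import numpy as np

ENERGY_GRID_KEV = np.array([ 10.,  15.,  20.,  30.,  40.,  50.,  60.,  80., 100., 150.])

ATOMIC_MASS = {'H': 1.008, 'C': 12.011, 'N': 14.007, 'O': 15.999, 'Na': 22.99, 'Mg': 24.305, 'Al': 26.982, 'P': 30.974, 'S': 32.06, 'Cl': 35.45, 'Ar': 39.948, 'K': 39.098, 'Ca': 40.078}
ATOMIC_NUMBER = {'H': 1, 'C': 6, 'N': 7, 'O': 8, 'Na': 11, 'Mg': 12, 'Al': 13, 'P': 15, 'S': 16, 'Cl': 17, 'Ar': 18, 'K': 19, 'Ca': 20}

# per element: photoelectric, incoherent, coherent, mu_en (cm^2/g)
ELEMENTS = {
    "H": {
        "photoelectric": np.array([0.000276087, 0.0001882, 0.00018475, 0.0001785, 0.0001729, 0.00016775, 0.000163, 0.000332187, 0.000594083, 0.000837835]),
        "incoherent": np.array([0.382639, 0.374518, 0.367652, 0.355215, 0.344071, 0.333823, 0.32437, 0.307555, 0.292928, 0.263775]),
        "coherent": np.array([0.00248478, 0.0016938, 0.00166275, 0.0016065, 0.0015561, 0.00150975, 0.001467, 0.00121331, 0.000877917, 0.000487665]),
        "mu_en": np.array([0.00986, 0.011, 0.01331, 0.01864, 0.02315, 0.02709, 0.03053, 0.0362, 0.04063, 0.04813]),
    },
    "C": {
        "photoelectric": np.array([2.10557, 0.576364, 0.228728, 0.0612563, 0.0234825, 0.0109346, 0.00559738, 0.00171867, 0.000513453, 0.00012496]),
        "incoherent": np.array([0.192674, 0.189212, 0.18591, 0.179745, 0.174103, 0.168919, 0.16414, 0.155616, 0.148234, 0.13345]),
        "coherent": np.array([0.0747545, 0.0415246, 0.0273617, 0.0151989, 0.010015, 0.00724654, 0.00556311, 0.0036657, 0.00265239, 0.00112464]),
        "mu_en": np.array([2.078, 0.5627, 0.2238, 0.06614, 0.03343, 0.02397, 0.02098, 0.02037, 0.02147, 0.02449]),
    },
    "N": {
        "photoelectric": np.array([3.599, 0.998244, 0.399877, 0.109041, 0.0429359, 0.020553, 0.0109991, 0.00394113, 0.00150837, 0.000179403]),
        "incoherent": np.array([0.192754, 0.18929, 0.185987, 0.17982, 0.174175, 0.168989, 0.164208, 0.15568, 0.148296, 0.133506]),
        "coherent": np.array([0.0872499, 0.0484655, 0.0319353, 0.0177394, 0.011689, 0.00845782, 0.006493, 0.00427843, 0.00309574, 0.00161462]),
        "mu_en": np.array([3.60261, 1.00346, 0.406582, 0.118398, 0.054585, 0.0341917, 0.0263738, 0.0221757, 0.0219737, 0.0244188]),
    },
    "O": {
        "photoelectric": np.array([5.65937, 1.59118, 0.64249, 0.177694, 0.0708606, 0.0344442, 0.018975, 0.0071396, 0.00318071, 0.000552539]),
        "incoherent": np.array([0.192862, 0.189397, 0.186092, 0.179921, 0.174273, 0.169084, 0.1643, 0.155768, 0.148379, 0.133581]),
        "coherent": np.array([0.0997703, 0.0554203, 0.0365181, 0.020285, 0.0133664, 0.00967152, 0.00742475, 0.00489239, 0.00353998, 0.00196639]),
        "mu_en": np.array([5.565, 1.545, 0.6179, 0.1729, 0.0753, 0.04414, 0.03207, 0.02468, 0.02355, 0.02506]),
    },
    "Na": {
        "photoelectric": np.array([15.0427, 4.46595, 1.86263, 0.536256, 0.220604, 0.110424, 0.0626764, 0.0255962, 0.0127179, 0.00349206]),
        "incoherent": np.array([0.184546, 0.18123, 0.178067, 0.172162, 0.166758, 0.161793, 0.157215, 0.149051, 0.141981, 0.127821]),
        "coherent": np.array([0.131268, 0.0729169, 0.0480471, 0.0266891, 0.0175863, 0.0127249, 0.0097688, 0.00643695, 0.00465758, 0.00258719]),
        "mu_en": np.array([15.0462, 4.47094, 1.86905, 0.545215, 0.231757, 0.123482, 0.0773964, 0.0430543, 0.0323117, 0.0266993]),
    },
    "Mg": {
        "photoelectric": np.array([20.5206, 6.09226, 2.54092, 0.731538, 0.300939, 0.150636, 0.0855006, 0.0349173, 0.0173492, 0.00476373]),
        "incoherent": np.array([0.19043, 0.187008, 0.183745, 0.177652, 0.172075, 0.166952, 0.162228, 0.153804, 0.146508, 0.131897]),
        "coherent": np.array([0.147768, 0.0820821, 0.0540863, 0.0300438, 0.0197967, 0.0143243, 0.0109967, 0.00724603, 0.00524301, 0.00291238]),
        "mu_en": np.array([20.5242, 6.09741, 2.54754, 0.740782, 0.312447, 0.164111, 0.10069, 0.0529321, 0.0375679, 0.028711]),
    },
    "Al": {
        "photoelectric": np.array([25.888, 7.68573, 3.20551, 0.922877, 0.379651, 0.190036, 0.107864, 0.0440502, 0.0218871, 0.00600971]),
        "incoherent": np.array([0.185831, 0.182492, 0.179308, 0.173362, 0.16792, 0.16292, 0.158311, 0.15009, 0.14297, 0.128711]),
        "coherent": np.array([0.156216, 0.0867749, 0.0571785, 0.0317615, 0.0209286, 0.0151433, 0.0116254, 0.00766031, 0.00554277, 0.00307889]),
        "mu_en": np.array([25.8914, 7.69077, 3.21198, 0.931898, 0.390882, 0.203185, 0.122686, 0.0616299, 0.0416174, 0.0293787]),
    },
    "P": {
        "photoelectric": np.array([40.152, 11.9205, 4.97173, 1.43138, 0.588837, 0.294745, 0.167296, 0.0683215, 0.0339467, 0.00932103]),
        "incoherent": np.array([0.186786, 0.18343, 0.180229, 0.174252, 0.168782, 0.163757, 0.159124, 0.15086, 0.143704, 0.129372]),
        "coherent": np.array([0.181175, 0.100639, 0.0663141, 0.0368361, 0.0242724, 0.0175628, 0.0134828, 0.00888421, 0.00642835, 0.00357081]),
        "mu_en": np.array([40.1555, 11.9256, 4.97823, 1.44044, 0.600125, 0.307962, 0.182195, 0.0859916, 0.0537784, 0.03281]),
    },
    "S": {
        "photoelectric": np.array([49.6154, 14.73, 6.1435, 1.76873, 0.727618, 0.364213, 0.206726, 0.0844241, 0.0419475, 0.0115179]),
        "incoherent": np.array([0.192489, 0.189031, 0.185732, 0.179573, 0.173936, 0.168757, 0.163983, 0.155467, 0.148092, 0.133323]),
        "coherent": np.array([0.199155, 0.110626, 0.0728949, 0.0404916, 0.0266811, 0.0193056, 0.0148208, 0.00976585, 0.00706627, 0.00392517]),
        "mu_en": np.array([49.619, 14.7352, 6.1502, 1.77808, 0.739251, 0.377833, 0.222079, 0.102634, 0.0623847, 0.0357241]),
    },
    "Cl": {
        "photoelectric": np.array([56.5402, 16.7859, 7.00095, 2.01559, 0.829172, 0.415046, 0.235578, 0.0962071, 0.0478021, 0.0131254]),
        "incoherent": np.array([0.184962, 0.181639, 0.178469, 0.172551, 0.167134, 0.162158, 0.15757, 0.149387, 0.142301, 0.128109]),
        "coherent": np.array([0.203327, 0.112944, 0.0744221, 0.0413399, 0.0272401, 0.0197101, 0.0151313, 0.00997046, 0.00721432, 0.00400741]),
        "mu_en": np.array([56.5436, 16.7909, 7.00738, 2.02457, 0.84035, 0.428133, 0.250332, 0.113705, 0.0674401, 0.036385]),
    },
    "Ar": {
        "photoelectric": np.array([62.3924, 18.5233, 7.72559, 2.22422, 0.914996, 0.458006, 0.259962, 0.106165, 0.0527499, 0.014484]),
        "incoherent": np.array([0.173791, 0.170668, 0.16769, 0.162129, 0.15704, 0.152364, 0.148053, 0.140365, 0.133707, 0.120372]),
        "coherent": np.array([0.202285, 0.112365, 0.0740407, 0.0411281, 0.0271005, 0.0196091, 0.0150537, 0.00991936, 0.00717735, 0.00398687]),
        "mu_en": np.array([62.3957, 18.528, 7.73163, 2.23266, 0.925499, 0.470303, 0.273824, 0.122606, 0.0712019, 0.0363388]),
    },
    "K": {
        "photoelectric": np.array([78.3442, 23.2592, 9.70078, 2.79288, 1.14893, 0.575103, 0.326426, 0.133308, 0.0662364, 0.0181871]),
        "incoherent": np.array([0.187434, 0.184066, 0.180855, 0.174857, 0.169368, 0.164326, 0.159676, 0.151384, 0.144203, 0.129822]),
        "coherent": np.array([0.230286, 0.127919, 0.0842894, 0.046821, 0.0308517, 0.0223234, 0.0171375, 0.0112924, 0.00817084, 0.00453873]),
        "mu_en": np.array([78.3477, 23.2642, 9.7073, 2.80198, 1.16026, 0.588366, 0.341377, 0.15104, 0.0861369, 0.0417576]),
    },
    "Ca": {
        "photoelectric": np.array([92.9386, 27.592, 11.5079, 3.31316, 1.36296, 0.682237, 0.387235, 0.158142, 0.0785753, 0.0215751]),
        "incoherent": np.array([0.192475, 0.189016, 0.185718, 0.179559, 0.173923, 0.168745, 0.16397, 0.155455, 0.148081, 0.133313]),
        "coherent": np.array([0.248925, 0.138272, 0.0911118, 0.0506107, 0.0333489, 0.0241302, 0.0185246, 0.0122064, 0.00883218, 0.00490609]),
        "mu_en": np.array([92.9422, 27.5972, 11.5146, 3.3225, 1.37459, 0.695856, 0.402587, 0.17635, 0.099011, 0.0457794]),
    },
}

# material-level mass energy-absorption overrides (trusted compilations)
MUEN_OVERRIDES = {
    "air": np.array([4.742, 1.334, 0.5389, 0.1537, 0.06833, 0.04098, 0.03041, 0.02407, 0.02325, 0.02496]),
    "water": np.array([4.944, 1.374, 0.5503, 0.1557, 0.06947, 0.04223, 0.0319, 0.02597, 0.02546, 0.02764]),
}
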