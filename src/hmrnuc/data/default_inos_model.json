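{
 "feature_names": [
  "1mer_A",
  "1mer_C",
  "2mer_AA",
  "2mer_AC",
  "2mer_AG",
  "2mer_AT",
  "2mer_CA",
  "2mer_CC",
  "2mer_CG",
  "2mer_GA",
  "2mer_GC",
  "2mer_TA",
  "3mer_AAA",
  "3mer_AAC",
  "3mer_AAG",
  "3mer_AAT",
  "3mer_ACA",
  "3mer_ACC",
  "3mer_ACG",
  "3mer_ACT",
  "3mer_AGA",
  "3mer_AGC",
  "3mer_AGG",
  "3mer_ATA",
  "3mer_ATC",
  "3mer_ATG",
  "3mer_CAA",
  "3mer_CAC",
  "3mer_CAG",
  "3mer_CCA",
  "3mer_CCC",
  "3mer_CCG",
  "3mer_CGA",
  "3mer_CGC",
  "3mer_CTA",
  "3mer_CTC",
  "3mer_GAA",
  "3mer_GAC",
  "3mer_GCA",
  "3mer_GCC",
  "3mer_GGA",
  "3mer_GTA",
  "3mer_TAA",
  "3mer_TCA",
  "4mer_AAAA",
  "4mer_AAAC",
  "4mer_AAAG",
  "4mer_AAAT",
  "4mer_AACA",
  "4mer_AACC",
  "4mer_AACG",
  "4mer_AACT",
  "4mer_AAGA",
  "4mer_AAGC",
  "4mer_AAGG",
  "4mer_AAGT",
  "4mer_AATA",
  "4mer_AATC",
  "4mer_AATG",
  "4mer_AATT",
  "4mer_ACAA",
  "4mer_ACAC",
  "4mer_ACAG",
  "4mer_ACAT",
  "4mer_ACCA",
  "4mer_ACCC",
  "4mer_ACCG",
  "4mer_ACCT",
  "4mer_ACGA",
  "4mer_ACGC",
  "4mer_ACGG",
  "4mer_ACGT",
  "4mer_ACTA",
  "4mer_ACTC",
  "4mer_ACTG",
  "4mer_AGAA",
  "4mer_AGAC",
  "4mer_AGAG",
  "4mer_AGAT",
  "4mer_AGCA",
  "4mer_AGCC",
  "4mer_AGCG",
  "4mer_AGCT",
  "4mer_AGGA",
  "4mer_AGGC",
  "4mer_AGGG",
  "4mer_AGTA",
  "4mer_AGTC",
  "4mer_AGTG",
  "4mer_ATAA",
  "4mer_ATAC",
  "4mer_ATAG",
  "4mer_ATAT",
  "4mer_ATCA",
  "4mer_ATCC",
  "4mer_ATCG",
  "4mer_ATGA",
  "4mer_ATGC",
  "4mer_ATGG",
  "4mer_ATTA",
  "4mer_ATTC",
  "4mer_ATTG",
  "4mer_CAAA",
  "4mer_CAAC",
  "4mer_CAAG",
  "4mer_CACA",
  "4mer_CACC",
  "4mer_CACG",
  "4mer_CAGA",
  "4mer_CAGC",
  "4mer_CAGG",
  "4mer_CATA",
  "4mer_CATC",
  "4mer_CATG",
  "4mer_CCAA",
  "4mer_CCAC",
  "4mer_CCAG",
  "4mer_CCCA",
  "4mer_CCCC",
  "4mer_CCCG",
  "4mer_CCGA",
  "4mer_CCGC",
  "4mer_CCGG",
  "4mer_CCTA",
  "4mer_CCTC",
  "4mer_CGAA",
  "4mer_CGAC",
  "4mer_CGAG",
  "4mer_CGCA",
  "4mer_CGCC",
  "4mer_CGCG",
  "4mer_CGGA",
  "4mer_CGGC",
  "4mer_CGTA",
  "4mer_CGTC",
  "4mer_CTAA",
  "4mer_CTAC",
  "4mer_CTAG",
  "4mer_CTCA",
  "4mer_CTCC",
  "4mer_CTGA",
  "4mer_CTGC",
  "4mer_CTTA",
  "4mer_CTTC",
  "4mer_GAAA",
  "4mer_GAAC",
  "4mer_GACA",
  "4mer_GACC",
  "4mer_GAGA",
  "4mer_GAGC",
  "4mer_GATA",
  "4mer_GATC",
  "4mer_GCAA",
  "4mer_GCAC",
  "4mer_GCCA",
  "4mer_GCCC",
  "4mer_GCGA",
  "4mer_GCGC",
  "4mer_GCTA",
  "4mer_GGAA",
  "4mer_GGAC",
  "4mer_GGCA",
  "4mer_GGCC",
  "4mer_GGGA",
  "4mer_GGTA",
  "4mer_GTAA",
  "4mer_GTAC",
  "4mer_GTCA",
  "4mer_GTGA",
  "4mer_GTTA",
  "4mer_TAAA",
  "4mer_TACA",
  "4mer_TAGA",
  "4mer_TATA",
  "4mer_TCAA",
  "4mer_TCCA",
  "4mer_TCGA",
  "4mer_TGAA",
  "4mer_TGCA",
  "4mer_TTAA",
  "gc_fraction"
 ],
 "weights": [
  -35.25849615132062,
  6.6304173212424166e-12,
  -0.0,
  -8.45674615807709,
  -31.583443075683217,
  -7.561153391375061,
  43.36586448202711,
  26.07357073512636,
  18.966013683095575,
  -35.40582903393037,
  -0.0,
  14.272236335031565,
  -0.0,
  8.346927184053122,
  43.357182113215785,
  -0.15527704953640992,
  -0.0,
  -177.38705873125062,
  0.0,
  0.0,
  67.7412097675713,
  96.89063033965118,
  -139.0260553895112,
  11.714889048166823,
  -23.404182568119726,
  18.814277325538377,
  -35.1147395917763,
  -4.583343949596046,
  -21.661643253874104,
  26.036614946940354,
  240.89739104059208,
  3.494559565304419,
  14.99262003792966,
  -63.84967246834088,
  -0.0,
  -6.285168332941957,
  28.033802311184115,
  2.6754262267447335,
  39.11205671888329,
  -130.5038393832632,
  -64.55045476785659,
  -13.167154758056297,
  -0.0,
  -47.16366209771471,
  6.435669134085329,
  -3.6351151382274005,
  33.848684245917134,
  47.180322899047354,
  0.28097100235799627,
  67.52052903268579,
  11.3565090911824,
  -0.8302954544558289,
  7.075981946801091,
  -141.54509361388008,
  37.56338125007802,
  9.265544114287833,
  8.931056838989686,
  24.75190633993735,
  -28.333685352105306,
  -34.19248536896426,
  42.89413998702194,
  -47.267937792241945,
  21.268378271582552,
  -28.628774186862493,
  90.36003799712017,
  60.935964180389874,
  -68.4661224373067,
  83.24084882101386,
  -90.87944718075153,
  -0.0,
  18.8956451190431,
  -82.97103333856151,
  18.52873686243381,
  72.32581083795837,
  -9.406203269662685,
  -76.53999652309139,
  -75.14880611456226,
  -99.02876803520638,
  -68.16381360553645,
  -2.4139113402495234,
  56.378389768191866,
  -18.964754733485794,
  -20.704280524592974,
  46.223476832650015,
  40.536151777958324,
  -264.42976008677846,
  -24.16918169661107,
  -38.66527742881621,
  -47.40407328613333,
  -44.060399122707835,
  -52.65890873940193,
  -27.660449994850385,
  -95.19786865899611,
  17.401401345600533,
  23.965517670256254,
  -0.0,
  9.853947597087231,
  -109.8796064523508,
  -120.23219171643703,
  31.488097874932546,
  10.418251387125359,
  -33.03813386796073,
  -68.76918761538327,
  -55.697584994597875,
  -53.520683252145005,
  -9.122272195508351,
  95.35296009060778,
  29.35794231087971,
  -11.7786845858207,
  -89.39922320222976,
  117.5578855980898,
  0.0,
  6.577990251271803,
  -12.790452882852753,
  -62.099408706849964,
  -38.45519879270077,
  -24.24916347040396,
  -329.6948769538095,
  -141.65704630355293,
  -270.56424319057714,
  34.752056490365824,
  238.59295072783888,
  242.26550303733276,
  82.97922112466622,
  185.80815542145203,
  22.41335468810351,
  96.0405385230004,
  55.80877873745888,
  -3.2786004508839124,
  297.3616242159468,
  13.164706852871564,
  -91.88748390018192,
  -84.93042144675121,
  -0.21092837797652467,
  58.42388957344681,
  7.222443797220032,
  11.978585901633746,
  64.38780730499292,
  -2.240374541062654,
  40.19210143708588,
  43.67077643524508,
  -32.15305323356195,
  -0.0,
  -0.7201995332406257,
  -42.16738653884188,
  -22.59272827434778,
  -28.428850614679174,
  146.7139612507474,
  61.752981823303465,
  -29.982684668204268,
  56.08658217914511,
  64.26305541242102,
  -42.56977887476693,
  -67.80360035765875,
  -0.0,
  183.23413726549256,
  -21.053476655063125,
  183.30015689595095,
  -111.07724051474052,
  10.79018310067557,
  73.80345986000485,
  93.71317606421998,
  342.7861953839746,
  34.58054025062125,
  76.16602092772287,
  -21.53080588463257,
  -6.720712774305394,
  2.214664245098024,
  -3.3876999095391187,
  -4.640267401076738,
  -11.05190215507532,
  -0.0,
  14.542578715718415,
  63.4653272817038,
  88.79046048287071,
  43.09311960619143,
  -118.32698361468884,
  0.0,
  18.95377591505043,
  -35.685487998313754,
  -5.110349752978526
 ],
 "intercept": 27.68149613777939,
 "lambda": 0.0005,
 "n_train": 8000,
 "seed": 42,
 "metadata": {
  "trained_on": "occupancy_track",
  "sample_n": 8000,
  "synthetic": true,
  "note": "Default model trained on a synthetic sequence-driven occupancy track (sequence_driven_dataset seed=42, scale=0.4). Not derived from any experimental corpus."
 }
}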