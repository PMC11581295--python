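# Match lexicon: one rule per line, tab-separated.
# columns: axis, priority, pattern (regex on normalized sentence text), label
# Within an axis the highest-priority matching rule wins; priorities are
# unique per axis.  Patterns run on lowercased text with punctuation
# collapsed to single spaces ("temporo-parietal" -> "temporo parietal").
category	60	glioblastoma|astrocytoma|oligodendroglioma|\bglioma\b|meningioma|ependymoma|medulloblastoma|schwannoma|pituitary adenoma|craniopharyngioma	primary brain tumour
category	50	metasta|carcinoma|melanoma	probable metastasis
category	40	demyelinat|abscess|encephalitis|radiation necrosis|\bcyst\b|granuloma	other brain lesions
category	30	gliosis|reactive change|unremarkable brain|no diagnostic abnormality	miscellaneous lesions
category	20	infarct|hematoma|haematoma|hemorrhage|haemorrhage|aneurysm|arteriovenous malformation|cavernoma|amyloid angiopathy	brain cardiovascular disease
subtype	40	(?<!non )small cell	small cell carcinoma
subtype	31	adenocarcinoma	adenocarcinoma
subtype	30	squamous	squamous cell carcinoma
subtype	10	non small cell	non-small cell carcinoma NOS
primary_site	60	\blung\b|pulmonary|bronchogenic	lung
primary_site	50	breast|mammary	breast
primary_site	40	melanoma	melanoma
primary_site	30	colorectal|\bcolon\b|colonic|rectal	colorectal
primary_site	20	renal|kidney	renal
primary_site	10	prostat|esophag|oesophag|gastric|ovarian|thyroid|hepatocell|pancrea|bladder|urothelial	other
location	70	\bfront	frontal
location	60	pariet	parietal
location	50	tempor	temporal
location	40	occipit	occipital
location	30	cerebell	cerebellum
location	20	brainstem|brain stem|thalam|basal ganglia|\bdura|\bpons\b|pontine|medulla|midbrain|corpus callosum|ventricle|ventricular|pineal|sella|sellar|insula	other
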