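# GERD-like symptoms: a 36-PT MedDRA query spanning reflux, esophagitis,
# esophageal structural damage, dysmotility, dyspepsia, nausea and vomiting.
# MedDRA has no standardized query for GERD, so the composite is defined
# explicitly at the preferred-term level.
name: GERD-like symptoms
preferred_terms:
  "10000059": Abdominal discomfort
  "10000060": Abdominal distension
  "10075494": Acid peptic disease
  "10007645": Cardiospasm
  "10013924": Dyskinesia oesophageal
  "10013946": Dyspepsia
  "10013950": Dysphagia
  "10063655": Erosive oesophagitis
  "10052405": Gastric hypomotility
  "10017885": Gastrooesophageal reflux disease
  "10062879": Gastrooesophageal sphincter insufficiency
  "10021518": Impaired gastric emptying
  "10028813": Nausea
  "10055668": Necrotising oesophagitis
  "10062501": Non-cardiac chest pain
  "10030136": Oesophageal achalasia
  "10053634": Oesophageal discomfort
  "10065835": Oesophageal fistula
  "10030172": Oesophageal haemorrhage
  "10070818": Oesophageal irritation
  "10072280": Oesophageal mucosa erythema
  "10030178": Oesophageal obstruction
  "10030180": Oesophageal pain
  "10030181": Oesophageal perforation
  "10052211": Oesophageal rupture
  "10030194": Oesophageal stenosis
  "10030201": Oesophageal ulcer
  "10030202": Oesophageal ulcer haemorrhage
  "10052488": Oesophageal ulcer perforation
  "10030216": Oesophagitis
  "10030219": Oesophagitis haemorrhagic
  "10056992": Oesophagobronchial fistula
  "10072163": Oesophagogastroduodenoscopy abnormal
  "10072166": Oesophagogastroscopy abnormal
  "10030223": Oesophagoscopy abnormal
  "10047700": Vomiting
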