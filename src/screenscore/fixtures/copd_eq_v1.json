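{
  "version": "copd_eq_v1",
  "items": [
    {
      "id": "item1",
      "name": "age",
      "text": "How old are you?",
      "choices": ["Aged 35-49", "Aged 50-59", "Aged 60-69", "Aged >=70"]
    },
    {
      "id": "item2",
      "name": "smoking_amount",
      "text": "How many cigarettes have you smoked? (packs per year)",
      "choices": ["0", "0-10", "10-20", ">20"]
    },
    {
      "id": "item3",
      "name": "bio_fuel",
      "text": "Have you been exposed to biomass smoke for more than half a year?",
      "choices": ["No", "Yes"]
    },
    {
      "id": "item4",
      "name": "short_breathe",
      "text": "During the past year, how much of time did you feel short of breath?",
      "choices": ["None of the time", "A little of the time", "Some of the time", "Most of the time", "All the time"]
    },
    {
      "id": "item5",
      "name": "dyspnoea",
      "text": "When do you have dyspnoea?",
      "choices": ["No dyspnoea", "During strenuous activities", "During walking quickly on the flat ground or climbing a small slope", "Slower than peers when walking on the flat ground, or needs to rest", "Severe dyspnoea leads to inability to leave home, or dyspnoea when wearing and undressing"]
    },
    {
      "id": "item6",
      "name": "cough",
      "text": "Do you often cough when you don't have a cold?",
      "choices": ["No", "Yes"]
    },
    {
      "id": "item7",
      "name": "cough_up",
      "text": "Have you ever coughed up something, such as mucus or sputum?",
      "choices": ["Never", "Yes, cough occasionally when having a cold or chest infection", "Yes, cough for a few days every month", "Yes, cough for most days", "Yes, cough every day"]
    },
    {
      "id": "item8",
      "name": "childhood_resp_disease",
      "text": "Did you suffer from chronic respiratory disease as a child?",
      "choices": ["No", "Yes"]
    },
    {
      "id": "item9",
      "name": "relatives_medical_history",
      "text": "Whether your first-degree relatives (parents, children, siblings) have a history of respiratory disease (such as chronic bronchitis, emphysema, asthma)?",
      "choices": ["No", "Yes"]
    }
  ]
}
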