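# Packaged clinical phrase lexicon: surface<TAB>pos
# pos in {noun, verb, adjective, numeral_unit, time, negation, function, symbol}
# Dates, durations and number+unit readings are recognized by pattern, not here.
# --- negation / denial
否认	negation
无	negation
未	negation
# --- clinical verbs
出现	verb
诉	verb
给予	verb
予	verb
行	verb
进行	verb
复查	verb
随访	verb
治疗	verb
入院	verb
出院	verb
就诊	verb
诊断	verb
服用	verb
测定	verb
化验	verb
抗感染	verb
抗炎	verb
收入院	verb
转入	verb
再次入院	verb
复诊	verb
好转出院	verb
# --- outcome / evaluation terms
无效	adjective
有效	adjective
好转	adjective
缓解	adjective
加重	adjective
未见异常	adjective
正常	adjective
明显好转	adjective
无明显诱因	adjective
# --- diseases / history items
肝炎	noun
结核	noun
疟疾病	noun
疟疾	noun
高血压	noun
冠心病	noun
糖尿病	noun
哮喘	noun
胃炎	noun
肺炎	noun
肾炎	noun
贫血	noun
心律失常	noun
甲亢	noun
骨折	noun
胆囊炎	noun
阑尾炎	noun
胃溃疡	noun
支气管炎	noun
鼻炎	noun
脑梗死	noun
手术	noun
外伤	noun
输血	noun
药物过敏	noun
# --- symptoms
咽痛	noun
发热	noun
头痛	noun
咳嗽	noun
腹痛	noun
乏力	noun
胸闷	noun
恶心	noun
呕吐	noun
腹泻	noun
头晕	noun
心悸	noun
气促	noun
食欲不振	noun
畏寒	noun
盗汗	noun
咳痰	noun
胸痛	noun
关节痛	noun
皮疹	noun
水肿	noun
便血	noun
尿频	noun
腰痛	noun
失眠	noun
# --- drugs
阿奇霉素	noun
头孢呋辛	noun
阿莫西林	noun
布洛芬	noun
奥美拉唑	noun
二甲双胍	noun
阿司匹林	noun
氨氯地平	noun
左氧氟沙星	noun
对乙酰氨基酚	noun
硝苯地平	noun
美托洛尔	noun
泼尼松	noun
地塞米松	noun
甲硝唑	noun
# --- examinations / panels
检查	noun
血常规	noun
尿常规	noun
便常规	noun
肝功能	noun
肾功能	noun
心电图	noun
胸片	noun
血糖	noun
血脂	noun
电解质	noun
甲状腺功能	noun
腹部超声	noun
胸部CT	noun
头颅MRI	noun
凝血功能	noun
# --- vital signs / measurement nouns (valid KV keys)
体温	noun
脉搏	noun
呼吸	noun
血压	noun
心率	noun
体重	noun
身高	noun
# --- section headers
主诉	noun
现病史	noun
既往史	noun
个人史	noun
家族史	noun
入院诊断	noun
出院诊断	noun
查体	noun
辅助检查	noun
诊疗经过	noun
用药	noun
医嘱	noun
# --- places / misc nouns
医院	noun
我院	noun
门诊	noun
急诊	noun
病房	noun
患者	noun
症状	noun
感染	noun
病情	noun
# --- function morphemes
史	function
病史	function
在	function
于	function
的	function
后	function
前	function
因	function
及	function
并	function
等	function
较	function
再次	function
门诊随访	verb
对症治疗	verb
抗感染治疗	verb
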