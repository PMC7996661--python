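surface	normalized_label	kind	is_status
student	student	title	1
unemployed	unemployed	title	1
retired	retired	title	1
carer	carer	title	1
self-employed	self-employed	title	1
self employed	self-employed	title	1
homemaker	homemaker	title	1
housewife	homemaker	title	1
volunteer	volunteer	title	1
builder	builder	title	0
teacher	teacher	title	0
accountant	accountant	title	0
electrician	electrician	title	0
plumber	plumber	title	0
carpenter	carpenter	title	0
chef	chef	title	0
cook	cook	title	0
waiter	waiter	title	0
waitress	waiter	title	0
barista	barista	title	0
bartender	bartender	title	0
cleaner	cleaner	title	0
hairdresser	hairdresser	title	0
barber	barber	title	0
mechanic	mechanic	title	0
engineer	engineer	title	0
architect	architect	title	0
solicitor	solicitor	title	0
lawyer	lawyer	title	0
barrister	barrister	title	0
paralegal	paralegal	title	0
librarian	librarian	title	0
journalist	journalist	title	0
photographer	photographer	title	0
designer	designer	title	0
graphic designer	graphic designer	title	0
web developer	web developer	title	0
software developer	software developer	title	0
programmer	programmer	title	0
analyst	analyst	title	0
banker	banker	title	0
cashier	cashier	title	0
shop assistant	shop assistant	title	0
retail worker	retail worker	title	0
sales assistant	sales assistant	title	0
salesperson	salesperson	title	0
estate agent	estate agent	title	0
receptionist	receptionist	title	0
secretary	secretary	title	0
administrator	administrator	title	0
civil servant	civil servant	title	0
clerk	clerk	title	0
postman	postman	title	0
courier	courier	title	0
delivery driver	delivery driver	title	0
bus driver	bus driver	title	0
taxi driver	taxi driver	title	0
lorry driver	lorry driver	title	0
train driver	train driver	title	0
driver	driver	title	0
pilot	pilot	title	0
security guard	security guard	title	0
police officer	police officer	title	0
firefighter	firefighter	title	0
soldier	soldier	title	0
farmer	farmer	title	0
gardener	gardener	title	0
landscaper	landscaper	title	0
decorator	decorator	title	0
painter	painter	title	0
plasterer	plasterer	title	0
roofer	roofer	title	0
bricklayer	bricklayer	title	0
scaffolder	scaffolder	title	0
welder	welder	title	0
machinist	machinist	title	0
factory worker	factory worker	title	0
warehouse operative	warehouse operative	title	0
forklift driver	forklift driver	title	0
butcher	butcher	title	0
baker	baker	title	0
greengrocer	greengrocer	title	0
florist	florist	title	0
jeweller	jeweller	title	0
tailor	tailor	title	0
dressmaker	dressmaker	title	0
musician	musician	title	0
singer	singer	title	0
actor	actor	title	0
artist	artist	title	0
writer	writer	title	0
editor	editor	title	0
translator	translator	title	0
interpreter	interpreter	title	0
lecturer	lecturer	title	0
tutor	tutor	title	0
teaching assistant	teaching assistant	title	0
childminder	childminder	title	0
nanny	nanny	title	0
care assistant	care assistant	title	0
dentist	dentist	title	0
optician	optician	title	0
pharmacist	pharmacist	title	0
vet	vet	title	0
veterinary surgeon	vet	title	0
accounts clerk	accounts clerk	title	0
bookkeeper	bookkeeper	title	0
surveyor	surveyor	title	0
plant operator	plant operator	title	0
miner	miner	title	0
fisherman	fisherman	title	0
sailor	sailor	title	0
chauffeur	chauffeur	title	0
porter	porter	title	0
caretaker	caretaker	title	0
window cleaner	window cleaner	title	0
refuse collector	refuse collector	title	0
traffic warden	traffic warden	title	0
dinner lady	dinner lady	title	0
shopkeeper	shopkeeper	title	0
market trader	market trader	title	0
hawker	market trader	title	0
sex worker	sex worker	title	0
drug dealer	drug dealer	title	0
dj	dj	title	0
model	model	title	0
sportsman	sportsman	title	0
footballer	footballer	title	0
boxer	boxer	title	0
personal trainer	personal trainer	title	0
fitness instructor	fitness instructor	title	0
driving instructor	driving instructor	title	0
pastor	pastor	title	0
priest	priest	title	0
imam	imam	title	0
hgv driver	lorry driver	title	0
it consultant	it consultant	title	0
recruiter	recruiter	title	0
project manager	project manager	title	0
manager	manager	title	0
supervisor	supervisor	title	0
foreman	foreman	title	0
apprentice	apprentice	title	0
intern	intern	title	0
psychiatrist	psychiatrist	title	0
consultant psychiatrist	psychiatrist	title	0
doctor	doctor	title	0
gp	doctor	title	0
physician	doctor	title	0
surgeon	surgeon	title	0
nurse	nurse	title	0
psychiatric nurse	psychiatric nurse	title	0
mental health nurse	psychiatric nurse	title	0
community psychiatric nurse	psychiatric nurse	title	0
cpn	psychiatric nurse	title	0
midwife	midwife	title	0
paramedic	paramedic	title	0
therapist	therapist	title	0
psychotherapist	psychotherapist	title	0
occupational therapist	occupational therapist	title	0
physiotherapist	physiotherapist	title	0
psychologist	psychologist	title	0
counsellor	counsellor	title	0
social worker	social worker	title	0
support worker	support worker	title	0
key worker	key worker	title	0
care coordinator	care coordinator	title	0
construction	construction	description	0
catering	catering	description	0
hospitality	hospitality	description	0
retail	retail	description	0
accounting	accounting	description	0
plumbing	plumbing	description	0
carpentry	carpentry	description	0
hairdressing	hairdressing	description	0
cleaning	cleaning	description	0
security	security	description	0
administration	administration	description	0
marketing	marketing	description	0
sales	sales	description	0
finance	finance	description	0
teaching	teaching	description	0
engineering	engineering	description	0
farming	farming	description	0
childcare	childcare	description	0
decorating	decorating	description	0
landscaping	landscaping	description	0
scaffolding	scaffolding	description	0
bar work	bar work	description	0
office work	office work	description	0
factory work	factory work	description	0
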